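"""Unit and property tests for the isolated excitatory-inhibitory pair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcfield.core_model import (
    ConfigurationError,
    PointParams,
    TYPE_I_PARAMS,
    TYPE_II_PARAMS,
    find_fixed_points,
    jacobian,
    jacobian_eigenvalues,
    lfp_of,
    measure_oscillation,
    point_derivatives,
    sigmoid,
    simulate_point,
)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    @given(st.floats(-1e3, 1e3))
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry(self, u):
        assert sigmoid(u) + sigmoid(-u) == pytest.approx(1.0, abs=1e-12)

    def test_resting_drive_value(self):
        # the synaptic drive at the type II rest state
        assert sigmoid(-4.045) == pytest.approx(0.0172084, abs=1e-6)

    def test_overflow_safe(self):
        assert sigmoid(1000.0) == 1.0
        assert sigmoid(-1000.0) == 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            sigmoid(float("nan"))


class TestDerivatives:
    def test_zero_at_rest(self, type_ii):
        d = point_derivatives((0.017, 0.020), type_ii)
        assert abs(d[0]) < 1e-3 and abs(d[1]) < 1e-3

    def test_decoupled_equilibrium(self):
        p = PointParams(k_ee=0, k_ei=0, k_ie=0, k_ii=0, b_e=0, b_i=0)
        d = point_derivatives((0.5, 0.5), p)
        assert d == (0.0, 0.0)

    def test_growth_from_origin(self, type_ii):
        d = point_derivatives((0.0, 0.0), type_ii)
        assert d[0] > 0 and d[1] > 0

    def test_lfp_weighting(self):
        assert lfp_of(1.0, 0.0) == pytest.approx(0.8)
        assert lfp_of(0.0, 1.0) == pytest.approx(0.2)
        assert lfp_of(0.017, 0.020) == pytest.approx(0.0176)


class TestIntegration:
    def test_limit_cycle_at_driven_current(self, type_ii):
        traj = simulate_point(type_ii.replace(J_e=2.0), init=(0.017, 0.020),
                              duration=600.0, dt=0.02)
        m = measure_oscillation(traj, discard=200.0)
        assert m.oscillating and m.amplitude > 0.1

    def test_convergence_to_rest(self, type_ii):
        traj = simulate_point(type_ii, init=(0.5, 0.5), duration=100.0, dt=0.02)
        assert traj.U_e[-1] == pytest.approx(0.017, abs=1e-3)
        assert traj.U_i[-1] == pytest.approx(0.020, abs=1e-3)

    def test_step_halving(self, type_ii):
        p = type_ii.replace(J_e=2.0)
        a = simulate_point(p, init=(0.1, 0.1), duration=50.0, dt=0.02)
        b = simulate_point(p, init=(0.1, 0.1), duration=50.0, dt=0.01)
        assert abs(a.U_e[-1] - b.U_e[-1]) < 1e-4

    def test_fourth_order_convergence(self, type_ii):
        """Endpoint error scales ~dt^4 for the RK4 scheme."""
        p = type_ii.replace(J_e=2.0)
        dts = [0.2, 0.1, 0.05, 0.025]
        ref = simulate_point(p, init=(0.1, 0.1), duration=20.0, dt=0.003125)
        errs = []
        for dt in dts:
            t = simulate_point(p, init=(0.1, 0.1), duration=20.0, dt=dt)
            errs.append(abs(t.U_e[-1] - ref.U_e[-1]) + 1e-300)
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 3.5 < slope < 4.5

    def test_dt_guard(self, type_ii):
        with pytest.raises(ConfigurationError):
            simulate_point(type_ii, duration=10.0, dt=0.5)

    def test_lfp_identity_on_samples(self, type_ii):
        traj = simulate_point(type_ii.replace(J_e=2.0), init=(0.3, 0.1),
                              duration=50.0, dt=0.02)
        assert np.allclose(traj.lfp, 0.8 * traj.U_e + 0.2 * traj.U_i)

    @given(
        st.floats(5.0, 20.0), st.floats(5.0, 20.0), st.floats(5.0, 20.0),
        st.floats(1.0, 10.0), st.floats(0.0, 8.0), st.floats(0.0, 8.0),
        st.floats(0.05, 0.95), st.floats(0.05, 0.95),
    )
    @settings(deadline=None, derandomize=True, max_examples=15)
    def test_boundedness(self, kee, kei, kie, kii, be, bi, u0, v0):
        """The sigmoid bounds the attracting set: states stay in (0,1)^2."""
        p = PointParams(k_ee=kee, k_ei=kei, k_ie=kie, k_ii=kii, b_e=be, b_i=bi,
                        J_e=1.0, J_i=0.5)
        traj = simulate_point(p, init=(u0, v0), duration=60.0, dt=0.05)
        assert np.all(traj.U_e > 0) and np.all(traj.U_e < 1)
        assert np.all(traj.U_i > 0) and np.all(traj.U_i < 1)


class TestFixedPoints:
    def test_type_ii_rest(self, type_ii):
        fps = find_fixed_points(type_ii)
        assert len(fps) == 1
        fp = fps[0]
        assert fp.stable
        assert fp.U_e == pytest.approx(0.017, abs=5e-4)
        assert fp.U_i == pytest.approx(0.020, abs=5e-4)

    def test_type_i_rest_among_roots(self, type_i):
        fps = find_fixed_points(type_i)
        stable = [f for f in fps if f.stable]
        assert len(fps) == 3 and len(stable) == 1
        assert stable[0].U_e < 0.05  # low-rate rest state

    def test_decoupled_unique_root(self):
        p = PointParams(k_ee=0, k_ei=0, k_ie=0, k_ii=0, b_e=0, b_i=0)
        fps = find_fixed_points(p)
        assert len(fps) == 1
        assert fps[0].state == pytest.approx((0.5, 0.5), abs=1e-10)

    def test_roots_satisfy_flow(self, type_i):
        for fp in find_fixed_points(type_i):
            d = point_derivatives(fp.state, type_i)
            assert np.hypot(*d) < 1e-8

    def test_eigenvalues_match_stability_flag(self, type_i):
        for fp in find_fixed_points(type_i):
            eig = jacobian_eigenvalues(type_i, fp.state)
            assert (max(e.real for e in eig) < 0) == fp.stable

    def test_eigenvalue_precondition(self, type_ii):
        with pytest.raises(ValueError):
            jacobian_eigenvalues(type_ii, (0.5, 0.5))

    def test_decoupled_jacobian_limit(self):
        # all weights zero, huge thresholds: F' -> 0, eigenvalues -> -1/tau
        p = PointParams(k_ee=0, k_ei=0, k_ie=0, k_ii=0, b_e=50, b_i=50,
                        tau_e=2.0, tau_i=4.0)
        eig = np.linalg.eigvals(jacobian(p, (0.0, 0.0)))
        assert sorted(eig.real) == pytest.approx([-0.5, -0.25], abs=1e-6)

    def test_stability_agrees_with_simulation(self):
        """Sign of max Re(eigenvalue) predicts convergence of a perturbed run."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            p = PointParams(
                k_ee=rng.uniform(5, 20), k_ei=rng.uniform(5, 20),
                k_ie=rng.uniform(5, 20), k_ii=rng.uniform(1, 10),
                b_e=rng.uniform(0, 8), b_i=rng.uniform(0, 8),
                J_e=rng.uniform(0, 2), J_i=rng.uniform(0, 2),
            )
            fps = find_fixed_points(p)
            fp = fps[0]
            lam = max(e.real for e in fp.eigenvalues)
            if abs(lam) < 0.01:  # skip near-marginal draws
                continue
            traj = simulate_point(p, init=(fp.U_e + 1e-3, fp.U_i), duration=120.0,
                                  dt=0.05, store_every=20)
            final_dist = np.hypot(traj.U_e[-1] - fp.U_e, traj.U_i[-1] - fp.U_i)
            if lam < 0:
                assert final_dist < 1e-3
            else:
                assert final_dist > 1e-3
            checked += 1


class TestOscillationMeasure:
    def test_pure_tone(self):
        t = np.arange(0, 1000, 0.5)
        m = measure_oscillation((t, np.sin(2 * np.pi * 50 * t / 1000.0)), discard=200.0)
        assert m.frequency_hz == pytest.approx(50.0, rel=1e-3)

    def test_gamma_band_at_drive(self, type_ii):
        traj = simulate_point(type_ii.replace(J_e=2.0), init=(0.017, 0.020),
                              duration=700.0, dt=0.02)
        m = measure_oscillation(traj, discard=200.0)
        assert 40.0 <= m.frequency_hz <= 80.0

    def test_constant_trajectory(self):
        t = np.arange(0, 1000, 0.5)
        m = measure_oscillation((t, np.full_like(t, 0.3)), discard=200.0)
        assert m.amplitude == 0.0 and not m.oscillating

    def test_exports_roundtrip(self, type_ii, tmp_path):
        traj = simulate_point(type_ii, init=(0.3, 0.3), duration=20.0, dt=0.02)
        csv = tmp_path / "t.csv"
        traj.to_csv(csv)
        import pandas as pd

        df = pd.read_csv(csv)
        assert list(df.columns) == ["time_ms", "Ue", "Ui", "LFP"]
        assert len(df) == len(traj.times)
        h5 = tmp_path / "t.h5"
        traj.to_hdf5(h5)
        import h5py

        with h5py.File(h5) as f:
            assert np.allclose(f["point/Ue"][()], traj.U_e)
            assert f["point"].attrs["tau_e"] == type_ii.tau_e
        toml_text = type_ii.to_toml()
        import tomllib

        parsed = tomllib.loads(toml_text)
        assert parsed["point"]["k_ee"] == 15.0
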