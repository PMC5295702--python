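"""Tests for kernels, spatial convolution and the 1D field integrator."""

import numpy as np
import pytest

from wcfield.core_model import ConfigurationError, simulate_point
from wcfield.spatial_field import (
    FieldParams,
    StimulusSpec,
    convolve_field,
    convolve_field_direct,
    make_kernel,
    rest_state,
    simulate_field,
    simulate_field_batch,
)


class TestKernel:
    @pytest.mark.parametrize("sigma,k,dx", [(0.2, 15.0, 0.01), (0.1, 7.0, 0.02),
                                            (0.3, 1.0, 0.05)])
    def test_mass(self, sigma, k, dx):
        ker = make_kernel(sigma, k, dx)
        assert ker.sum() * dx == pytest.approx(k, rel=1e-3)

    def test_symmetry(self):
        ker = make_kernel(0.2, 15.0, 0.01)
        assert len(ker) % 2 == 1
        assert np.allclose(ker, ker[::-1])

    def test_peak_value(self):
        ker = make_kernel(0.2, 15.0, 0.01)
        assert ker.max() == pytest.approx(15.0 / (0.2 * np.sqrt(np.pi)), rel=1e-12)

    def test_coarse_dx_rejected(self):
        with pytest.raises(ConfigurationError):
            make_kernel(0.1, 7.0, 0.05)

    def test_short_truncation_rejected(self):
        with pytest.raises(ConfigurationError):
            make_kernel(0.2, 15.0, 0.01, truncate=2.0)


class TestConvolution:
    def test_constant_field_interior(self):
        ker = make_kernel(0.2, 15.0, 0.02)
        n = 200
        out = convolve_field(ker, np.full(n, 0.3), 0.02, pad_value=0.3)
        assert np.allclose(out, 0.3 * ker.sum() * 0.02, rtol=1e-6)

    def test_delta_recovers_kernel(self):
        ker = make_kernel(0.1, 7.0, 0.02)
        n = 301
        f = np.zeros(n)
        f[150] = 1.0 / 0.02  # discrete delta of unit integral
        out = convolve_field(ker, f, 0.02)
        m = len(ker) // 2
        assert np.allclose(out[150 - m:150 + m + 1], ker)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        f = rng.random(120)
        ker = make_kernel(0.1, 7.0, 0.02)
        fast = convolve_field(ker, f, 0.02, pad_value=0.25)
        slow = convolve_field_direct(ker, f, 0.02, pad_value=0.25)
        assert np.abs(fast - slow).max() < 1e-10

    def test_batch_axis(self):
        rng = np.random.default_rng(4)
        f = rng.random((3, 80))
        ker = make_kernel(0.1, 7.0, 0.02)
        out = convolve_field(ker, f, 0.02, pad_value=0.1)
        for b in range(3):
            assert np.allclose(out[b], convolve_field(ker, f[b], 0.02, pad_value=0.1))


class TestFieldParams:
    def test_dx_guard(self):
        with pytest.raises(ConfigurationError):
            FieldParams(dx=0.05, sigma_i=0.1)

    def test_spread_ratio_warning(self):
        with pytest.warns(UserWarning):
            FieldParams(sigma_e=0.2, sigma_i=0.2, dx=0.02)

    def test_point_projection(self, field_coarse):
        p = field_coarse.point()
        assert p.k_ee == field_coarse.k_ee and p.tau_i == field_coarse.tau_i


class TestFieldIntegration:
    def test_unstimulated_field_stays_at_rest(self, field_coarse):
        traj = simulate_field(field_coarse, StimulusSpec(J_e=0.0), 200.0,
                              dt=0.05, store_every=50)
        assert np.abs(traj.U_e - traj.U_e[0]).max() < 1e-6

    def test_states_bounded(self, mode_locking_trajs):
        traj = mode_locking_trajs[3.0]
        assert traj.U_e.min() > 0 and traj.U_e.max() < 1
        assert traj.U_i.min() > 0 and traj.U_i.max() < 1

    def test_mirror_symmetry(self, field_coarse):
        traj = simulate_field(field_coarse.replace(tau_e=0.4),
                              StimulusSpec(J_e=1.3), 120.0, dt=0.02, store_every=100)
        assert np.abs(traj.U_e - traj.U_e[:, ::-1]).max() < 1e-6

    def test_translation_equivariance(self, field_coarse):
        shift_mm = 0.5
        shift = int(round(shift_mm / field_coarse.dx))
        a = simulate_field(field_coarse.replace(tau_e=0.4),
                           StimulusSpec(J_e=1.3, center=0.0), 120.0,
                           dt=0.02, store_every=100)
        b = simulate_field(field_coarse.replace(tau_e=0.4),
                           StimulusSpec(J_e=1.3, center=shift_mm), 120.0,
                           dt=0.02, store_every=100)
        # compare away from the sponges
        sel = (np.abs(a.grid) <= 1.5)
        shifted = np.roll(b.U_e, -shift, axis=1)
        assert np.abs(a.U_e[:, sel] - shifted[:, sel]).max() < 1e-3

    def test_homogeneous_periodic_matches_point_model(self, field_coarse):
        """Uniform stimulation + periodic ends reduce to the isolated pair."""
        stim = StimulusSpec(J_e=2.0, width=2 * field_coarse.half_length + 1.0)
        traj = simulate_field(field_coarse, stim, 100.0, dt=0.02,
                              store_every=50, boundary="periodic")
        point = simulate_point(field_coarse.point(J_e=2.0),
                               init=rest_state(field_coarse),
                               duration=100.0, dt=0.02, store_every=50)
        for i_t in (10, 50, -1):
            assert np.abs(traj.U_e[i_t] - point.U_e[i_t]).max() < 1e-6

    def test_dt_guard(self, field_coarse):
        with pytest.raises(ConfigurationError):
            simulate_field(field_coarse.replace(tau_e=0.2), StimulusSpec(J_e=1.0),
                           50.0, dt=0.05)

    def test_batch_matches_single(self, field_coarse):
        batch = simulate_field_batch(field_coarse, StimulusSpec(J_e=1.3), 60.0,
                                     dt=0.05, store_every=20,
                                     tau_e=np.array([0.5, 2.0]), tau_i=4.0)
        single = simulate_field(field_coarse.replace(tau_e=0.5),
                                StimulusSpec(J_e=1.3), 60.0, dt=0.05, store_every=20)
        assert np.allclose(batch[0].U_e, single.U_e)

    def test_ramp_schedule_applied(self, field_coarse):
        # stimulus off for the first half: field must stay at rest there
        stim = StimulusSpec(J_e=1.3, ramp=((0.0, 0.0), (50.0, 0.0), (60.0, 1.0)))
        traj = simulate_field(field_coarse.replace(tau_e=0.4), stim, 150.0,
                              dt=0.02, store_every=100)
        early = traj.times <= 45.0
        assert np.abs(traj.U_e[early] - traj.U_e[0]).max() < 1e-6
        assert traj.U_e[-1].max() > 0.1

    def test_hdf5_roundtrip(self, field_coarse, tmp_path):
        traj = simulate_field(field_coarse, StimulusSpec(J_e=1.0), 20.0,
                              dt=0.05, store_every=20)
        path = tmp_path / "f.h5"
        traj.to_hdf5(path)
        import h5py

        with h5py.File(path) as f:
            assert np.allclose(f["Ue"][()], traj.U_e)
            assert np.allclose(f["LFP"][()], traj.lfp)
            assert f.attrs["stim_J_e"] == 1.0
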