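"""Tests for Hopf/SNIC detection, branch diagrams and the Hopf curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcfield.bifurcation import (
    NoHopfError,
    branch_diagram,
    classify_excitability,
    hopf_curve,
    hopf_curve_intersection,
    hopf_onset,
    ji_sigmoid,
    max_real_part,
    refine_fixed_point,
    snic_onset,
)
from wcfield.core_model import find_fixed_points


def _dense_scan_crossing(params, lo, hi, step=1e-4):
    """Brute-force oracle: finest sign change of max Re(lambda) on a grid."""
    fps = find_fixed_points(params.replace(J_e=lo))
    root = np.array(next(f for f in fps if f.stable).state)
    prev = None
    v = lo
    while v <= hi:
        p = params.replace(J_e=v)
        root = refine_fixed_point(p, root)
        if root is None:
            return None
        re, _ = max_real_part(p, root)
        if prev is not None and np.sign(re) != np.sign(prev):
            return v - step / 2
        prev = re
        v += step
    return None


class TestJiSigmoid:
    def test_zero_maps_to_zero(self):
        assert ji_sigmoid(0.0, 3.0) == 0.0

    def test_saturation(self):
        assert ji_sigmoid(1e3, 3.0) == pytest.approx(4.0, abs=1e-12)

    def test_reference_value(self):
        assert ji_sigmoid(1.0, 3.0) == pytest.approx(3.620593, abs=1e-6)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.5, 5.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_odd(self, a, b, beta):
        if a < b:
            assert ji_sigmoid(a, beta) < ji_sigmoid(b, beta)
        assert ji_sigmoid(-a, beta) == pytest.approx(-ji_sigmoid(a, beta), abs=1e-12)


class TestHopfOnset:
    def test_type_ii_onset_exists_in_gamma_band(self, type_ii):
        h = hopf_onset(type_ii, "J_e", (0.0, 2.0))
        assert 0.0 < h.value < 2.0
        assert 40.0 <= h.frequency_hz <= 80.0

    def test_agrees_with_dense_scan(self, type_ii):
        h = hopf_onset(type_ii, "J_e", (0.0, 2.0))
        brute = _dense_scan_crossing(type_ii, h.value - 0.05, h.value + 0.05)
        assert brute is not None
        assert abs(h.value - brute) < 1e-3

    def test_real_part_vanishes_at_onset(self, type_ii):
        h = hopf_onset(type_ii, "J_e", (0.0, 2.0))
        root = refine_fixed_point(type_ii.replace(J_e=h.value), h.state)
        re, im = max_real_part(type_ii.replace(J_e=h.value), root)
        assert abs(re) < 1e-6 and im > 0

    def test_no_hopf_reported(self, type_ii):
        with pytest.raises(NoHopfError):
            hopf_onset(type_ii, "J_e", (0.0, 0.5))

    def test_snic_branch_termination_detected(self, type_i):
        with pytest.raises(NoHopfError):
            hopf_onset(type_i, "J_e", (0.0, 3.0))

    def test_snic_onset_located(self, type_i):
        s = snic_onset(type_i, "J_e", (0.0, 3.0))
        below = find_fixed_points(type_i.replace(J_e=s.value - 1e-3))
        above = find_fixed_points(type_i.replace(J_e=s.value + 1e-3))
        assert len(below) == 3 and len(above) == 1
        # the merging saddle-node pair is close together just below onset
        pts = sorted((f.U_e, f.U_i) for f in below)
        gaps = [np.hypot(pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1])
                for i in range(2)]
        assert min(gaps) < 1e-1

    def test_focal_conversion_recovers_type_ii_onset(self, type_i, type_ii):
        """J_i = 4 into the b_i = 8 medium is exactly the b_i = 4 pair."""
        h1 = hopf_onset(type_i.replace(J_i=4.0), "J_e", (0.0, 3.0))
        h2 = hopf_onset(type_ii, "J_e", (0.0, 3.0))
        assert h1.value == pytest.approx(h2.value, abs=1e-6)


class TestBranchDiagram:
    def test_gradual_envelope_growth_type_ii(self, type_ii):
        h = hopf_onset(type_ii, "J_e", (0.0, 2.0))
        grid = np.linspace(h.value - 0.05, h.value + 0.5, 23)
        res = branch_diagram(type_ii, grid)
        w = res.envelope_width
        below = grid < h.value
        assert np.all(w[below] < 1e-3)
        # amplitude grows from ~0: first point past onset far below the plateau
        past = np.where(~below)[0]
        assert w[past[1]] < 0.5 * w[-1]

    def test_explosive_envelope_growth_high_ratio(self, type_ii):
        p = type_ii.replace(tau_e=0.32)  # tau_i/tau_e = 12.5
        h = hopf_onset(p, "J_e", (0.5, 1.5))
        grid = np.linspace(h.value - 0.05, h.value + 0.5, 23)
        res = branch_diagram(p, grid, dt=0.02)
        w = res.envelope_width
        first_osc = np.argmax(w > 1e-3)
        assert w[first_osc] > 0.5 * w[-1]  # jumps straight to the plateau

    def test_no_oscillation_below_onset(self, type_ii):
        res = branch_diagram(type_ii, np.linspace(0.0, 0.8, 9))
        assert np.all(res.envelope_width < 1e-3)
        assert np.all(np.isnan(res.frequency_hz))

    def test_critical_point_detected(self, type_ii):
        h = hopf_onset(type_ii, "J_e", (0.0, 2.0))
        res = branch_diagram(type_ii, np.linspace(1.0, 1.6, 7))
        kinds = [c.kind for c in res.critical_points]
        assert "hopf" in kinds
        hopf_pt = next(c for c in res.critical_points if c.kind == "hopf")
        assert hopf_pt.value == pytest.approx(h.value, abs=1e-6)


class TestClassification:
    def test_type_ii_supercritical(self, type_ii):
        label, diag = classify_excitability(type_ii, "J_e", (0.0, 3.0))
        assert label == "typeII_supercritical_hopf"
        assert diag.amplitude_sq_r2 > 0.95  # amplitude^2 linear in (J - J*)
        assert np.nanmin(diag.onset_frequencies_hz) > 10.0

    def test_type_i_snic(self, type_i):
        label, diag = classify_excitability(type_i, "J_e", (0.0, 3.0))
        assert label == "typeI_snic"
        assert diag.period_sqrt_r2 > 0.9  # period ~ (J - J*)^(-1/2)
        # frequency approaches zero at onset
        assert diag.onset_frequencies_hz[0] < 10.0

    def test_converted_medium_is_type_ii(self, type_i):
        label, _ = classify_excitability(type_i.replace(J_i=4.0), "J_e", (0.0, 3.0))
        assert label == "typeII_supercritical_hopf"


@pytest.fixture(scope="module")
def curve(type_i):
    return hopf_curve(type_i, np.arange(3.0, 6.01, 0.25))


class TestHopfCurve:

    def test_reuses_hopf_onset(self, curve, type_i):
        h = hopf_onset(type_i.replace(J_i=4.0), "J_e", (0.0, 3.0))
        i = np.argmin(np.abs(curve.J_i - 4.0))
        assert curve.J_e[i] == pytest.approx(h.value, abs=1e-7)

    def test_point_verified_by_dense_scan(self, curve, type_i):
        i = np.argmin(np.abs(curve.J_i - 4.5))
        p = type_i.replace(J_i=float(curve.J_i[i]))
        brute = _dense_scan_crossing(p, curve.J_e[i] - 0.05, curve.J_e[i] + 0.05)
        assert abs(curve.J_e[i] - brute) < 1e-3

    def test_low_ji_failures_are_flagged(self, type_i):
        c = hopf_curve(type_i, np.arange(0.5, 2.01, 0.5))
        assert len(c.failures) > 0  # SNIC region: no Hopf crossing

    def test_sigmoid_intersection_near_unity(self, curve):
        je = hopf_curve_intersection(curve, beta=3.0)
        assert je == pytest.approx(1.0, abs=0.3)
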