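"""Bifurcation analysis of the excitatory-inhibitory pair.

Locates oscillation onsets as external currents vary, builds one-parameter
branch diagrams (fixed points plus simulated limit-cycle envelopes),
classifies the excitability type of the onset, and continues the curve of
Hopf points through the (J_e, J_i) plane.

Excitability classes
--------------------
type II (supercritical Hopf)
    A stable spiral loses stability with a conjugate eigenvalue pair crossing
    the imaginary axis; oscillations are born at non-zero frequency with
    amplitude growing as sqrt(J - J*).
type I (SNIC)
    A saddle and a node merge on an invariant circle; the oscillation period
    diverges as (J - J*)^(-1/2), so arbitrarily low frequencies occur at
    onset while the amplitude is large from the start.

Hopf points are found by bisection on the largest eigenvalue real part of
the tracked fixed point — exact to machine precision for this 2-D system —
rather than by dedicated continuation software.  Envelopes come from direct
simulation, vectorised across the whole parameter grid in one pass.

The module also houses the sigmoidal stimulation coupling
``J_i = 8/(1+exp(-beta*J_e)) - 4`` that models how optogenetic drive
recruits the inhibitory population ahead of the excitatory one (zero at
zero drive, saturating at J_i = 4, the current that converts the type I
resting medium into a locally type II one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq, root as _scipy_root

from wcfield.core_model import (
    ConfigurationError,
    PointParams,
    find_fixed_points,
    jacobian,
    measure_oscillation,
    point_derivatives,
    simulate_point,
)

__all__ = [
    "NoHopfError",
    "OnsetPoint",
    "BifurcationResult",
    "HopfCurve",
    "ji_sigmoid",
    "JI_SATURATION",
    "refine_fixed_point",
    "max_real_part",
    "hopf_onset",
    "branch_diagram",
    "classify_excitability",
    "snic_onset",
    "hopf_curve",
    "hopf_curve_intersection",
]

#: Saturation level of the stimulation coupling; equals the inhibitory
#: current that converts the b_i = 8 medium back to type II.
JI_SATURATION = 4.0


class NoHopfError(RuntimeError):
    """No Hopf bifurcation in the scanned parameter range."""


def ji_sigmoid(J_e, beta: float):
    """Stimulation coupling ``J_i = 8/(1+exp(-beta*J_e)) - 4``.

    Odd in ``J_e`` (zero current maps to zero current) and saturating at
    +/- ``JI_SATURATION``.
    """
    J_e = np.asarray(J_e, dtype=float)
    out = 2.0 * JI_SATURATION / (1.0 + np.exp(-beta * J_e)) - JI_SATURATION
    return out if out.ndim else float(out)


def refine_fixed_point(params: PointParams, guess) -> Optional[np.ndarray]:
    """Newton-polish a fixed point from ``guess``; None if it diverges.

    Used to track a branch continuously during bisection, where a full
    multi-start search would be wasteful.  A refusal to converge, or a jump
    of more than 0.2 in state space, signals the end of the branch (e.g. a
    saddle-node annihilation) and returns None.
    """
    sol = _scipy_root(
        lambda s: np.asarray(point_derivatives(s, params)),
        x0=np.asarray(guess, float),
        jac=lambda s: jacobian(params, s),
        method="hybr",
        tol=1e-13,
    )
    # judge by the residual, not the success flag: hybr reports "no progress"
    # when started exactly on a marginal root
    if np.linalg.norm(np.asarray(point_derivatives(sol.x, params))) > 1e-9:
        return None
    if np.linalg.norm(sol.x - np.asarray(guess, float)) > 0.2:
        return None
    return sol.x


def max_real_part(params: PointParams, state) -> tuple[float, float]:
    """(max eigenvalue real part, |imag| at that eigenvalue) at ``state``."""
    eig = np.linalg.eigvals(jacobian(params, state))
    i = int(np.argmax(eig.real))
    return float(eig.real[i]), float(abs(eig.imag[i]))


@dataclass(frozen=True)
class OnsetPoint:
    """A critical parameter value where oscillations are born."""

    param: str
    value: float
    kind: Literal["hopf", "snic", "saddle_node"]
    frequency_hz: float  # onset frequency; 0 for a SNIC
    state: tuple  # fixed point at criticality


def _vary(params: PointParams, name: str, value: float) -> PointParams:
    if name not in ("J_e", "J_i"):
        raise ConfigurationError(f"can only vary J_e or J_i, not {name!r}")
    return params.replace(**{name: value})


def hopf_onset(
    params: PointParams,
    vary: str = "J_e",
    bracket: tuple[float, float] = (0.0, 2.0),
    tol: float = 1e-8,
) -> OnsetPoint:
    """Locate a Hopf bifurcation by bisection on the eigenvalue real part.

    The fixed point nearest the low-end rest state is tracked continuously
    across the bracket.  Raises :class:`NoHopfError` when the real part does
    not change sign, or when the branch terminates (saddle-node) before a
    complex-pair crossing occurs.
    """
    lo, hi = bracket
    fps = find_fixed_points(_vary(params, vary, lo))
    stable = [f for f in fps if f.stable]
    start = stable[0] if stable else fps[0]
    root = np.array(start.state)

    def tracked(value: float, guess):
        return refine_fixed_point(_vary(params, vary, value), guess)

    re_lo, _ = max_real_part(_vary(params, vary, lo), root)
    # march upward to find a sign change while the branch persists
    n_scan = 40
    grid = np.linspace(lo, hi, n_scan + 1)
    prev_v, prev_root, prev_re = lo, root, re_lo
    found = None
    for v in grid[1:]:
        r = tracked(v, prev_root)
        if r is None:
            raise NoHopfError(
                f"fixed-point branch terminates near {vary}={prev_v:.4g} "
                "(saddle-node?) before any Hopf crossing"
            )
        re, _ = max_real_part(_vary(params, vary, v), r)
        if np.sign(re) != np.sign(prev_re) and prev_re != 0.0:
            found = (prev_v, v, prev_root)
            break
        prev_v, prev_root, prev_re = v, r, re
    if found is None:
        raise NoHopfError(f"no eigenvalue real-part sign change for {vary} in {bracket}")

    a, b, root = found
    guess = root
    while b - a > tol:
        m = 0.5 * (a + b)
        r = tracked(m, guess)
        if r is None:  # branch lost inside the bracket: shrink from above
            b = m
            continue
        re, _ = max_real_part(_vary(params, vary, m), r)
        if np.sign(re) == np.sign(prev_re):
            a, guess = m, r
        else:
            b = m
    crit = 0.5 * (a + b)
    r = tracked(crit, guess)
    if r is None:
        r = guess
    re, im = max_real_part(_vary(params, vary, crit), r)
    if im <= 1e-6:
        raise NoHopfError(
            f"real-part sign change at {vary}={crit:.4g} has real eigenvalues "
            "(saddle-node, not Hopf)"
        )
    freq_hz = im * 1000.0 / (2.0 * np.pi)
    return OnsetPoint(param=vary, value=float(crit), kind="hopf",
                      frequency_hz=freq_hz, state=(float(r[0]), float(r[1])))


def snic_onset(
    params: PointParams,
    vary: str = "J_e",
    bracket: tuple[float, float] = (0.0, 3.0),
    tol: float = 1e-8,
) -> OnsetPoint:
    """Locate a saddle-node annihilation by bisection on the root count.

    On an invariant circle this is the SNIC onset: below the critical value
    the rest node and a saddle coexist (3 roots), above it only the
    repelling focus remains (1 root) and the limit cycle is global.
    """
    lo, hi = bracket

    def n_roots(v: float) -> int:
        return len(find_fixed_points(_vary(params, vary, v)))

    n_lo, n_hi = n_roots(lo), n_roots(hi)
    if n_lo == n_hi:
        raise NoHopfError(f"root count does not change over {bracket} ({n_lo} roots)")
    a, b = lo, hi
    while b - a > tol:
        m = 0.5 * (a + b)
        if n_roots(m) == n_lo:
            a = m
        else:
            b = m
    crit = 0.5 * (a + b)
    below = find_fixed_points(_vary(params, vary, crit - 10 * max(tol, 1e-7)))
    rest = [f for f in below if f.stable] or below
    st = rest[0].state
    return OnsetPoint(param=vary, value=float(crit), kind="snic",
                      frequency_hz=0.0, state=(float(st[0]), float(st[1])))


@dataclass
class BifurcationResult:
    """One-parameter branch diagram with simulated oscillation envelopes."""

    param: str
    grid: np.ndarray
    fixed_points: list  # per grid value: list of FixedPoint
    envelope_min: np.ndarray  # min of post-transient U_e
    envelope_max: np.ndarray
    frequency_hz: np.ndarray  # nan where not oscillating
    critical_points: list = field(default_factory=list)  # OnsetPoint

    @property
    def envelope_width(self) -> np.ndarray:
        return self.envelope_max - self.envelope_min

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.param: self.grid,
                "n_fixed_points": [len(f) for f in self.fixed_points],
                "n_stable": [sum(fp.stable for fp in f) for f in self.fixed_points],
                "envelope_min": self.envelope_min,
                "envelope_max": self.envelope_max,
                "frequency_hz": self.frequency_hz,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def branch_diagram(
    params: PointParams,
    grid,
    vary: str = "J_e",
    settle: float = 500.0,
    measure: float = 200.0,
    dt: float = 0.02,
    perturbation: tuple[float, float] = (0.1, 0.0),
    amp_threshold: float = 1e-4,
) -> BifurcationResult:
    """Fixed points, stability and cycle envelope over a parameter grid.

    Envelopes are measured by simulating every grid value simultaneously
    (vectorised batch) from a perturbed rest start: ``settle`` ms are
    discarded, the envelope and frequency taken from the following
    ``measure`` ms.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("grid must be strictly increasing")
    fps = [find_fixed_points(_vary(params, vary, v)) for v in grid]
    rest = []
    for flist in fps:
        stab = [f for f in flist if f.stable]
        pick = stab[0] if stab else flist[0]
        rest.append(pick.state)
    rest = np.asarray(rest)  # (G, 2)
    init = (rest[:, 0] + perturbation[0], rest[:, 1] + perturbation[1])
    batch = simulate_point(
        _vary(params, vary, grid), init=init,
        duration=settle + measure, dt=dt, store_every=max(1, int(round(0.05 / dt))),
    )
    env_min = np.empty(len(grid))
    env_max = np.empty(len(grid))
    freq = np.full(len(grid), np.nan)
    for i in range(len(grid)):
        keep = batch.times >= settle
        ue = batch.U_e[keep, i]
        lfp = batch.lfp[keep, i]
        env_min[i], env_max[i] = float(ue.min()), float(ue.max())
        if lfp.max() - lfp.min() >= amp_threshold:
            try:
                m = measure_oscillation((batch.times[keep], lfp), discard=0.0,
                                        amp_threshold=amp_threshold)
                freq[i] = m.frequency_hz
            except Exception:
                pass
        else:
            env_min[i] = env_max[i] = float(ue[-1])  # settled: zero-width envelope
    result = BifurcationResult(
        param=vary, grid=grid, fixed_points=fps,
        envelope_min=env_min, envelope_max=env_max, frequency_hz=freq,
    )
    result.critical_points = _detect_critical_points(params, vary, grid, fps)
    return result


def _detect_critical_points(params, vary, grid, fps) -> list[OnsetPoint]:
    out = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        n_a, n_b = len(fps[i]), len(fps[i + 1])
        stable_a = any(f.stable for f in fps[i])
        stable_b = any(f.stable for f in fps[i + 1])
        if n_a != n_b:
            try:
                out.append(snic_onset(params, vary, (a, b)))
            except NoHopfError:
                pass
        elif stable_a != stable_b:
            try:
                out.append(hopf_onset(params, vary, (a, b)))
            except NoHopfError:
                pass
    return out


@dataclass(frozen=True)
class ExcitabilityDiagnostics:
    onset: OnsetPoint
    onset_frequencies_hz: np.ndarray  # just above onset, ascending distance
    scan_offsets: np.ndarray  # (J - J*) values used
    amplitudes: np.ndarray  # peak-to-peak U_e at the offsets
    amplitude_sq_r2: float  # R^2 of amplitude^2 ~ (J - J*)
    period_sqrt_r2: float  # R^2 of period ~ (J - J*)^(-1/2)
    hysteresis: float  # |up-sweep onset - down-sweep offset|


def _linfit_r2(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or np.allclose(y, y[0]):
        return 0.0
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def classify_excitability(
    params: PointParams,
    vary: str = "J_e",
    scan: tuple[float, float] = (0.0, 3.0),
    dt: float = 0.02,
) -> tuple[str, ExcitabilityDiagnostics]:
    """Classify the oscillation onset as type II (Hopf) or type I (SNIC).

    The onset is first located structurally (eigenvalue crossing vs
    fixed-point annihilation), then confirmed dynamically: a supercritical
    Hopf shows onset frequency bounded away from zero and squared amplitude
    growing linearly in the parameter excess; a SNIC shows the oscillation
    period diverging as the inverse square root of the excess.  A hysteresis
    probe (up- vs down-sweep with inherited initial conditions) guards
    against mistaking a subcritical onset for either; a discordant set of
    diagnostics yields the label ``"unclassified"``.
    """
    try:
        onset = hopf_onset(params, vary, scan)
    except NoHopfError:
        onset = snic_onset(params, vary, scan)

    jstar = onset.value
    span = scan[1] - scan[0]
    if onset.kind == "snic":
        # period scaling probed over a decade close to onset
        offsets = jstar + np.array([1e-3, 2e-3, 4e-3, 7e-3, 1e-2]) * span
    else:
        offsets = jstar + np.linspace(0.01, 0.1, 5) * span
    offsets = offsets[offsets <= scan[1] + 0.5 * span]
    rest = np.asarray(onset.state)
    batch = simulate_point(
        _vary(params, vary, offsets),
        init=(rest[0] + 0.1, rest[1]),
        duration=1500.0 if onset.kind == "snic" else 700.0,
        dt=dt, store_every=2,
    )
    freqs, amps = [], []
    for i in range(len(offsets)):
        try:
            m = measure_oscillation((batch.times, batch.U_e[:, i]), discard=300.0)
            freqs.append(m.frequency_hz)
            amps.append(m.amplitude)
        except Exception:
            freqs.append(np.nan)
            amps.append(0.0)
    freqs, amps = np.asarray(freqs), np.asarray(amps)
    dj = offsets - jstar
    ok = np.isfinite(freqs) & (amps > 1e-4)
    amp_r2 = _linfit_r2(dj[ok], amps[ok] ** 2) if ok.sum() >= 3 else 0.0
    per_r2 = (
        _linfit_r2(dj[ok] ** -0.5, 1000.0 / freqs[ok]) if ok.sum() >= 3 else 0.0
    )
    hyst = _hysteresis_probe(params, vary, jstar, span, dt)

    diag = ExcitabilityDiagnostics(
        onset=onset, onset_frequencies_hz=freqs, scan_offsets=dj,
        amplitudes=amps, amplitude_sq_r2=amp_r2, period_sqrt_r2=per_r2,
        hysteresis=hyst,
    )
    if hyst > 0.05 * span:
        return "unclassified", diag
    if onset.kind == "snic" and per_r2 > 0.9:
        return "typeI_snic", diag
    if onset.kind == "hopf" and np.nanmin(freqs) > 10.0 and amp_r2 > 0.8:
        return "typeII_supercritical_hopf", diag
    return "unclassified", diag


def _hysteresis_probe(params, vary, jstar, span, dt, n=7) -> float:
    """Up- vs down-sweep oscillation boundary with inherited initial states.

    Both sweeps run as one two-element batch: element 0 walks the grid
    upward, element 1 downward, each inheriting its own final state.
    """
    lo, hi = jstar - 0.1 * span, jstar + 0.1 * span
    grid = np.linspace(lo, hi, n)

    def start_state(v):
        fps = find_fixed_points(_vary(params, vary, v))
        stab = [f for f in fps if f.stable]
        return np.asarray((stab[0] if stab else fps[0]).state) + np.array([0.05, 0.0])

    state = np.stack([start_state(grid[0]), start_state(grid[-1])])  # (2, 2)
    osc_up = np.zeros(n, bool)
    osc_down = np.zeros(n, bool)
    for i in range(n):
        values = np.array([grid[i], grid[n - 1 - i]])
        traj = simulate_point(_vary(params, vary, values),
                              init=(state[:, 0], state[:, 1]),
                              duration=400.0, dt=dt, store_every=4)
        lfp = traj.lfp[traj.times >= 250.0]
        ptp = lfp.max(axis=0) - lfp.min(axis=0)
        osc_up[i], osc_down[n - 1 - i] = ptp[0] >= 1e-3, ptp[1] >= 1e-3
        state = np.stack([traj.U_e[-1], traj.U_i[-1]], axis=1)
    up_on = grid[osc_up][0] if osc_up.any() else hi
    down_on = grid[osc_down][0] if osc_down.any() else hi
    return float(abs(up_on - down_on))


@dataclass
class HopfCurve:
    """The locus of Hopf points in the (J_e, J_i) plane."""

    J_e: np.ndarray
    J_i: np.ndarray
    frequency_hz: np.ndarray
    failures: list = field(default_factory=list)  # (J_i, reason)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"J_e": self.J_e, "J_i": self.J_i, "onset_frequency_hz": self.frequency_hz}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def hopf_curve(
    params: PointParams,
    Ji_grid=None,
    Je_range: tuple[float, float] = (0.0, 3.0),
) -> HopfCurve:
    """Continue the Hopf curve: critical J_e for each J_i on the grid.

    Grid points where the loss of stability is not a Hopf crossing (e.g. the
    SNIC portion of the onset boundary at low J_i) are recorded in
    ``failures`` and left as gaps.
    """
    if Ji_grid is None:
        Ji_grid = np.arange(1.0, 6.01, 0.25)
    Je_c, Ji_c, freq, failures = [], [], [], []
    for ji in np.asarray(Ji_grid, float):
        try:
            onset = hopf_onset(params.replace(J_i=float(ji)), "J_e", Je_range)
        except NoHopfError as e:
            failures.append((float(ji), str(e)))
            continue
        Je_c.append(onset.value)
        Ji_c.append(float(ji))
        freq.append(onset.frequency_hz)
    return HopfCurve(
        J_e=np.asarray(Je_c), J_i=np.asarray(Ji_c),
        frequency_hz=np.asarray(freq), failures=failures,
    )


def hopf_curve_intersection(curve: HopfCurve, beta: float) -> float:
    """J_e where the stimulation sigmoid crosses the Hopf curve.

    The curve is interpolated as J_e*(J_i); the crossing solves
    ``ji_sigmoid(J_e, beta) = J_i`` along it.
    """
    if len(curve.J_e) < 2:
        raise ValueError("Hopf curve has fewer than 2 points")
    order = np.argsort(curve.J_i)
    ji, je = curve.J_i[order], curve.J_e[order]

    def gap(ji_val: float) -> float:
        je_crit = float(np.interp(ji_val, ji, je))
        # invert the sigmoid: J_e delivering this J_i
        x = np.clip((ji_val + JI_SATURATION) / (2 * JI_SATURATION), 1e-9, 1 - 1e-9)
        je_stim = -np.log(1.0 / x - 1.0) / beta
        return je_stim - je_crit

    vals = [gap(v) for v in ji]
    sign = np.sign(vals)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise ValueError("stimulation sigmoid does not cross the Hopf curve on the grid")
    i = int(idx[0])
    ji_cross = brentq(gap, ji[i], ji[i + 1], xtol=1e-10)
    return float(np.interp(ji_cross, ji, je))
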