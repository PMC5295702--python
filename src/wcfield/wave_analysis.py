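"""Quantitative wave metrics on field simulations.

Measures how far focally evoked gamma waves travel, classifies the
propagation regime (none / finite / indefinite), counts the n:1 mode-locking
ratio between the source oscillation and the emitted wavefronts, and tracks
wavefront speed.

Conventions follow the simulation analyses in this package:

* Propagation distance is the smallest |x| at which the post-transient
  maximum of U_e(x, t) falls below 0.05, symmetrised over the two sides of
  the stimulus.  Runs in which activity never falls below threshold before
  the absorbing layer are *censored* — operationally "indefinite"
  propagation.
* Wavefront timing uses the upstroke of the LFP through rest + 0.05 with
  linear sub-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from wcfield.core_model import UndersampledError, lfp_of
from wcfield.spatial_field import (
    FieldParams,
    FieldTrajectory,
    StimulusSpec,
    rest_state,
    simulate_field_batch,
)

__all__ = [
    "WaveMetrics",
    "PROPAGATION_THRESHOLD",
    "propagation_distance",
    "propagation_regime_sweep",
    "emission_ratio",
    "wave_speed",
    "wave_speed_xt",
    "front_crossing_times",
]

#: U_e level below which activity no longer counts as propagated.
PROPAGATION_THRESHOLD = 0.05


@dataclass
class WaveMetrics:
    """Summary metrics for one field simulation."""

    tau_ratio: float  # tau_i / tau_e
    propagation_distance: float  # mm
    censored: bool
    regime: str  # none | finite | indefinite
    emission_n: Optional[int] = None
    source_frequency_hz: Optional[float] = None
    speed_cm_s: Optional[float] = None
    speed_sd_cm_s: Optional[float] = None


def propagation_distance(
    traj: FieldTrajectory,
    threshold: float = PROPAGATION_THRESHOLD,
    settle: float = 100.0,
) -> tuple[float, bool]:
    """(distance mm, censored) for activity spreading from the centre.

    ``m(x) = max_t U_e(x, t)`` over post-``settle`` times; the distance is
    the smallest |x| with ``m(x) < threshold`` on each side, averaged.  If a
    side never drops below threshold inside the absorbing layer the run is
    censored at ``half_length - sponge_width``.
    """
    keep = traj.times >= settle
    if keep.sum() < 2:
        raise UndersampledError("trajectory too short for the requested settle time")
    m = traj.U_e[keep].max(axis=0)
    edge = traj.params.half_length - traj.params.sponge_width
    sides = []
    censored = False
    for sgn in (+1, -1):
        sel = sgn * traj.grid >= 0
        xs = np.abs(traj.grid[sel])
        order = np.argsort(xs)
        xs, ms = xs[order], m[sel][order]
        below = np.where(ms < threshold)[0]
        if len(below) and xs[below[0]] <= edge:
            sides.append(xs[below[0]])
        else:
            sides.append(edge)
            censored = True
    return float(np.mean(sides)), censored


def _classify_regime(distance: float, censored: bool, traj: FieldTrajectory) -> str:
    if censored:
        return "indefinite"
    stim_half = (traj.stim.width / 2.0) if traj.stim is not None else 0.2
    # the subthreshold halo of a driven but non-emitting region only reaches a
    # fraction of a kernel spread past the stimulus edge; anything further was
    # carried by waves
    if distance <= stim_half + 0.5 * traj.params.sigma_e:
        return "none"
    return "finite"


def _auto_dt(tau_min: float, cap: float = 0.05) -> float:
    """Largest convenient RK4 step respecting the tau/10 stability guard."""
    for dt in (0.05, 0.04, 0.025, 0.02, 0.01, 0.005, 0.002, 0.001):
        if dt <= min(cap, tau_min / 10.0) + 1e-12:
            return dt
    raise ValueError(f"no admissible dt for tau_min={tau_min}")


def propagation_regime_sweep(
    base: FieldParams,
    stim: StimulusSpec,
    ratios: Sequence[float],
    tau_i: float = 4.0,
    duration: float = 300.0,
    settle: float = 100.0,
    dt: Optional[float] = None,
    threshold: float = PROPAGATION_THRESHOLD,
) -> tuple[list[WaveMetrics], dict]:
    """Propagation metrics as a function of tau_i/tau_e.

    The inhibitory time constant stays fixed (default 4 ms, preserving the
    gamma frequency) while tau_e = tau_i/ratio varies.  All ratios integrate
    as one vectorised batch.  Returns the per-ratio metrics plus the grid
    intervals bracketing the none->finite and finite->indefinite
    transitions (None where the transition is not inside the grid).
    """
    ratios = np.asarray(sorted(ratios), float)
    tau_e = tau_i / ratios
    if dt is None:
        dt = _auto_dt(min(tau_e.min(), tau_i))
    store_every = max(1, int(round(0.5 / dt)))
    trajs = simulate_field_batch(base, stim, duration, dt=dt,
                                 store_every=store_every,
                                 tau_e=tau_e, tau_i=tau_i)
    metrics = []
    for ratio, traj in zip(ratios, trajs):
        # envelope distance includes the stimulus-onset response …
        dist, cens = propagation_distance(traj, threshold=threshold, settle=settle)
        # … but "indefinite" requires waves still arriving at the absorbing
        # layer late in the run, not a single onset transient
        _, late_cens = propagation_distance(traj, threshold=threshold,
                                            settle=2.0 * duration / 3.0)
        regime = "indefinite" if late_cens else _classify_regime(dist, False, traj)
        metrics.append(
            WaveMetrics(tau_ratio=float(ratio), propagation_distance=dist,
                        censored=late_cens, regime=regime)
        )
    regimes = [m.regime for m in metrics]
    boundaries = {"none_to_finite": None, "finite_to_indefinite": None}
    for i in range(len(ratios) - 1):
        if regimes[i] == "none" and regimes[i + 1] != "none":
            boundaries["none_to_finite"] = (float(ratios[i]), float(ratios[i + 1]))
        if regimes[i] != "indefinite" and regimes[i + 1] == "indefinite":
            boundaries["finite_to_indefinite"] = (float(ratios[i]), float(ratios[i + 1]))
    return metrics, boundaries


def emission_ratio(
    traj: FieldTrajectory,
    probe_offset: float = 1.5,
    settle: float = 100.0,
    min_cycles: int = 12,
    probe_amp_floor: float = 1e-3,
) -> tuple[Optional[int], float, bool]:
    """n:1 mode-locking ratio between source oscillation and emitted waves.

    Counts LFP peaks at the source (x = 0) and at ``probe_offset`` mm over
    the post-settle window (at least ``min_cycles`` source cycles) and
    returns ``(n, source_frequency_hz, confident)``.  ``n`` is None when the
    probe shows no waves (peak-to-peak below ``probe_amp_floor``).
    """
    keep = traj.times >= settle
    t = traj.times[keep]
    lfp = traj.lfp[keep]
    i_src = int(np.argmin(np.abs(traj.grid)))
    i_probe = int(np.argmin(np.abs(traj.grid - probe_offset)))
    src = lfp[:, i_src]
    src_amp = src.max() - src.min()
    if src_amp < 1e-3:
        raise UndersampledError("no sustained oscillation at the source")
    src_peaks, _ = find_peaks(src, prominence=0.1 * src_amp)
    if len(src_peaks) < min_cycles + 1:
        raise UndersampledError(
            f"only {len(src_peaks)} source cycles; need >= {min_cycles}"
        )
    period = float(np.mean(np.diff(t[src_peaks])))
    freq = 1000.0 / period
    probe = lfp[:, i_probe]
    probe_amp = probe.max() - probe.min()
    if probe_amp < probe_amp_floor:
        return None, freq, True
    probe_peaks, _ = find_peaks(probe, prominence=0.1 * probe_amp)
    if len(probe_peaks) < 2:
        return None, freq, True
    # count source cycles over an integer number of probe cycles, so a locked
    # n:1 ratio comes out exactly n
    t0, t1 = t[probe_peaks[0]], t[probe_peaks[-1]]
    n_probe = len(probe_peaks) - 1
    n_src = int(np.sum((t[src_peaks] >= t0) & (t[src_peaks] < t1)))
    if n_src < min_cycles:
        raise UndersampledError(
            f"only {n_src} source cycles inside the probe window; need >= {min_cycles}"
        )
    raw = n_src / n_probe
    n = int(round(raw))
    return max(n, 1), freq, bool(abs(raw - n) <= 0.1)


def one_to_one_threshold(
    base: FieldParams,
    ratios: Sequence[float] = (2.0, 2.25, 2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0),
    je_values: Sequence[float] = (2.0, 2.5, 3.0),
    ji: float = 4.0,
    tau_i: float = 4.0,
    duration: float = 450.0,
    settle: float = 100.0,
    dt: float = 0.05,
) -> tuple[Optional[float], dict]:
    """Smallest tau_i/tau_e admitting 1:1 wave emission in the converted medium.

    For each ratio, all stimulation currents in ``je_values`` (spanning the
    currents used throughout the study) run as one batch; a ratio qualifies
    when any current yields a consistently locked 1:1 count (count-ratio
    deviation within 0.1).  Returns (smallest qualifying ratio or None,
    per-ratio detail map {ratio: [(J_e, n, confident), ...]}).
    """
    detail: dict = {}
    smallest = None
    for ratio in sorted(ratios):
        trajs = simulate_field_batch(
            base, StimulusSpec(J_i=ji), duration, dt=dt,
            store_every=max(1, int(round(0.5 / dt))),
            stim_J_e=np.asarray(je_values, float), stim_J_i=ji,
            tau_e=tau_i / ratio, tau_i=tau_i,
        )
        cells = []
        hit = False
        for je, traj in zip(je_values, trajs):
            try:
                n, _, conf = emission_ratio(traj, settle=settle)
            except UndersampledError:
                n, conf = None, False
            cells.append((float(je), n, conf))
            hit = hit or (n == 1 and conf)
        detail[float(ratio)] = cells
        if hit and smallest is None:
            smallest = float(ratio)
    return smallest, detail


def front_crossing_times(times: np.ndarray, signal: np.ndarray, level: float) -> np.ndarray:
    """Upward threshold-crossing times with linear sub-sample interpolation."""
    s = np.asarray(signal, float)
    below = s[:-1] < level
    above = s[1:] >= level
    idx = np.where(below & above)[0]
    frac = (level - s[idx]) / (s[idx + 1] - s[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def wave_speed_xt(
    positions: np.ndarray,
    times: np.ndarray,
    lfp_xt: np.ndarray,
    band: tuple[float, float] = (1.0, 2.0),
    level: Optional[float] = None,
    rest_lfp: Optional[float] = None,
    settle: float = 100.0,
    min_fronts: int = 3,
) -> tuple[float, float, int]:
    """(mean, SD, n_fronts) of outward front speed in cm/s.

    ``lfp_xt`` is (n_times, n_positions); fronts are timed at the two
    positions nearest ``band`` and matched in order of passage.  ``level``
    defaults to ``rest_lfp + 0.05``.
    """
    positions = np.asarray(positions, float)
    x1, x2 = band
    if level is None:
        if rest_lfp is None:
            raise ValueError("provide either level or rest_lfp")
        level = rest_lfp + 0.05
    keep = times >= settle
    t = times[keep]
    i1 = int(np.argmin(np.abs(positions - x1)))
    i2 = int(np.argmin(np.abs(positions - x2)))
    d_mm = abs(positions[i2] - positions[i1])
    t1s = front_crossing_times(t, lfp_xt[keep, i1], level)
    t2s = front_crossing_times(t, lfp_xt[keep, i2], level)
    if len(t1s) < min_fronts or len(t2s) < min_fronts:
        raise UndersampledError(
            f"fewer than {min_fronts} fronts crossed the band "
            f"({len(t1s)} at x1, {len(t2s)} at x2)"
        )
    spacing = np.median(np.diff(t1s)) if len(t1s) > 1 else np.inf
    speeds = []
    for t1 in t1s:
        later = t2s[t2s > t1]
        if len(later) == 0:
            continue
        delta = later[0] - t1
        if delta <= 0 or delta >= spacing:
            continue
        speeds.append(d_mm / delta * 100.0)  # mm/ms -> cm/s
    if len(speeds) < min_fronts:
        raise UndersampledError(f"only {len(speeds)} matched fronts in the band")
    speeds = np.asarray(speeds)
    return float(speeds.mean()), float(speeds.std(ddof=1)), len(speeds)


def wave_speed(
    traj: FieldTrajectory,
    band: tuple[float, float] = (1.0, 2.0),
    settle: float = 100.0,
    min_fronts: int = 3,
) -> tuple[float, float, int]:
    """Outward wavefront speed (cm/s) in a field simulation.

    Tracks the LFP upstroke through rest + 0.05 between the two band edges
    on the positive-x side.  Returns (mean, SD, n_fronts).
    """
    ue_rest, ui_rest = rest_state(traj.params)
    level = float(lfp_of(ue_rest, ui_rest)) + 0.05
    return wave_speed_xt(traj.grid, traj.times, traj.lfp, band=band,
                         level=level, settle=settle, min_fronts=min_fronts)
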