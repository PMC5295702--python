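"""Ramped-stimulation protocols and spectral summaries.

Emulates the optogenetic ramp experiment: the excitatory current rises
linearly from 0 while the inhibitory current follows the sigmoidal
recruitment law ``J_i = 8/(1+exp(-beta*J_e)) - 4``, so both currents start
at zero and J_i saturates at 4 — the level that converts the type I resting
medium into a locally type II one.  Because the coupled path grazes the
Hopf curve near its crossing, the oscillation amplitude rises gradually,
and critical slowing delays the observable onset past the static critical
current.

The module also provides the baseline-subtracted spectrogram used to
visualise such ramps: short-time power in dB relative to the mean
pre-stimulation power of each frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import expit

from wcfield.bifurcation import ji_sigmoid, max_real_part, refine_fixed_point
from wcfield.core_model import (
    ConfigurationError,
    PointParams,
    find_fixed_points,
    lfp_of,
)
from wcfield.spatial_field import FieldParams, StimulusSpec, simulate_field

__all__ = [
    "RampResult",
    "run_ramp",
    "static_critical_current",
    "sliding_envelope",
    "spectrogram_db",
]


@dataclass
class RampResult:
    """Outcome of a ramped-stimulation run.

    ``onset_time`` is when the oscillation envelope first exceeds 5 % of its
    end-of-ramp value; ``static_onset_time`` is when the instantaneous J_e
    crosses the static critical current on the coupled (J_e, J_i) path.
    Critical slowing guarantees ``onset_time >= static_onset_time`` for an
    up-ramp.
    """

    times: np.ndarray  # ms
    J_e: np.ndarray
    J_i: np.ndarray
    lfp: np.ndarray
    envelope: np.ndarray  # sliding-window peak-to-peak of the LFP
    onset_time: float  # ms (nan if no oscillation)
    static_onset_time: float  # ms (nan if the ramp never crosses J_e*)
    static_J_e: float  # the static critical current itself
    direction: str
    beta: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.times, "J_e": self.J_e, "J_i": self.J_i,
             "LFP": self.lfp, "envelope": self.envelope}
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("times", "J_e", "J_i", "lfp", "envelope"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["onset_time_ms"] = self.onset_time
            f.attrs["static_onset_time_ms"] = self.static_onset_time
            f.attrs["static_J_e"] = self.static_J_e
            f.attrs["direction"] = self.direction
            f.attrs["beta"] = self.beta


def static_critical_current(
    params: PointParams,
    beta: float,
    bracket: tuple[float, float] = (0.0, 3.0),
    tol: float = 1e-8,
) -> float:
    """Static critical J_e along the coupled stimulation path.

    Bisects the largest eigenvalue real part of the tracked fixed point of
    the pair driven with ``(J_e, ji_sigmoid(J_e, beta))``.
    """

    def prepare(je: float) -> PointParams:
        return params.replace(J_e=float(je), J_i=float(ji_sigmoid(je, beta)))

    lo, hi = bracket
    fps = find_fixed_points(prepare(lo))
    stable = [f for f in fps if f.stable]
    root = np.array((stable[0] if stable else fps[0]).state)
    re_lo, _ = max_real_part(prepare(lo), root)
    # coarse march, then bisection
    grid = np.linspace(lo, hi, 40)
    prev, prev_root, prev_re = lo, root, re_lo
    span = None
    for v in grid[1:]:
        r = refine_fixed_point(prepare(v), prev_root)
        if r is None:
            span = (prev, v, prev_root)
            break
        re, _ = max_real_part(prepare(v), r)
        if np.sign(re) != np.sign(prev_re):
            span = (prev, v, prev_root)
            break
        prev, prev_root, prev_re = v, r, re
    if span is None:
        raise ConfigurationError(f"no loss of stability along the coupled path in {bracket}")
    a, b, guess = span
    while b - a > tol:
        m = 0.5 * (a + b)
        r = refine_fixed_point(prepare(m), guess)
        if r is None:
            b = m
            continue
        re, _ = max_real_part(prepare(m), r)
        if np.sign(re) == np.sign(prev_re):
            a, guess = m, r
        else:
            b = m
    return 0.5 * (a + b)


def sliding_envelope(times: np.ndarray, signal: np.ndarray, window: float = 50.0) -> np.ndarray:
    """Sliding-window peak-to-peak amplitude (window in ms, centred)."""
    dt = float(times[1] - times[0])
    half = max(1, int(round(window / dt / 2)))
    n = len(signal)
    env = np.empty(n)
    # running min/max via strided blocks would be fancier; direct windows are
    # fast enough at the stored sampling rate
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = signal[lo:hi]
        env[i] = seg.max() - seg.min()
    return env


def _ramp_point(params: PointParams, je_t, ji_t, duration, dt, store_every):
    """Fixed-step RK4 of the pair with time-varying currents."""
    n_steps = int(round(duration / dt))
    # currents at full and half steps
    tg = np.arange(n_steps + 1) * dt
    je_full, ji_full = je_t(tg), ji_t(tg)
    je_half, ji_half = je_t(tg[:-1] + 0.5 * dt), ji_t(tg[:-1] + 0.5 * dt)

    fps = find_fixed_points(params.replace(J_e=float(je_full[0]), J_i=float(ji_full[0])))
    stable = [f for f in fps if f.stable]
    ue, ui = (stable[0] if stable else fps[0]).state

    ke, ki_, kb_e, kb_i = params.k_ee, params.k_ei, params.b_e, params.b_i
    kie, kii = params.k_ie, params.k_ii
    te, ti = params.tau_e, params.tau_i

    def rhs(ue, ui, je, ji):
        due = (-ue + expit(ke * ue - ki_ * ui + je - kb_e)) / te
        dui = (-ui + expit(kie * ue - kii * ui + ji - kb_i)) / ti
        return due, dui

    stored = list(range(0, n_steps + 1, store_every))
    out = np.empty((len(stored), 2))
    out[0] = ue, ui
    j = 1
    for s in range(n_steps):
        k1e, k1i = rhs(ue, ui, je_full[s], ji_full[s])
        k2e, k2i = rhs(ue + 0.5 * dt * k1e, ui + 0.5 * dt * k1i, je_half[s], ji_half[s])
        k3e, k3i = rhs(ue + 0.5 * dt * k2e, ui + 0.5 * dt * k2i, je_half[s], ji_half[s])
        k4e, k4i = rhs(ue + dt * k3e, ui + dt * k3i, je_full[s + 1], ji_full[s + 1])
        ue += (dt / 6.0) * (k1e + 2 * k2e + 2 * k3e + k4e)
        ui += (dt / 6.0) * (k1i + 2 * k2i + 2 * k3i + k4i)
        if j < len(stored) and s + 1 == stored[j]:
            out[j] = ue, ui
            j += 1
    times = np.asarray(stored, float) * dt
    return times, out[:, 0], out[:, 1]


def run_ramp(
    params: Union[PointParams, FieldParams],
    beta: float = 3.0,
    J_e_end: float = 3.0,
    duration: float = 4000.0,
    direction: str = "up",
    baseline: float = 500.0,
    dt: float = 0.02,
    store_every: int = 25,
    onset_fraction: float = 0.05,
) -> RampResult:
    """Ramp J_e linearly over ``duration`` ms with J_i slaved to the sigmoid.

    A quiet ``baseline`` interval at the ramp's start current precedes the
    ramp (useful for baseline-subtracted spectrograms).  ``direction='down'``
    ramps from ``J_e_end`` to 0 instead.  For :class:`FieldParams` the ramp
    is applied focally through a piecewise-linear stimulus schedule and the
    LFP is read at the stimulus centre; for :class:`PointParams` the whole
    pair is driven.
    """
    if direction not in ("up", "down"):
        raise ConfigurationError("direction must be 'up' or 'down'")
    tau_i = params.tau_i
    if duration < 100.0 * tau_i:
        raise ConfigurationError("ramp must last at least 100 inhibitory time constants")
    total = baseline + duration

    def je_of_t(t):
        frac = np.clip((np.asarray(t, float) - baseline) / duration, 0.0, 1.0)
        if direction == "down":
            frac = 1.0 - frac
        return J_e_end * frac

    def ji_of_t(t):
        return ji_sigmoid(je_of_t(t), beta)

    if isinstance(params, FieldParams):
        # focal ramp: piecewise-linear schedules for J_e (exact) and J_i
        # (dense sampling of the sigmoid)
        tdense = np.linspace(0.0, total, 201)
        ramp_e = tuple((float(t), float(je_of_t(t) / J_e_end)) for t in tdense)
        ramp_i = tuple((float(t), float(ji_of_t(t) / ji_sigmoid(J_e_end, beta))) for t in tdense)
        stim = StimulusSpec(J_e=J_e_end, J_i=float(ji_sigmoid(J_e_end, beta)),
                            ramp=ramp_e, ramp_i=ramp_i)
        traj = simulate_field(params, stim, total, dt=dt, store_every=store_every)
        times = traj.times
        lfp = traj.lfp[:, int(np.argmin(np.abs(traj.grid - stim.center)))]
        base_params = params.point()
    else:
        times, ue, ui = _ramp_point(params, je_of_t, ji_of_t, total, dt, store_every)
        lfp = np.asarray(lfp_of(ue, ui))
        base_params = params

    env = sliding_envelope(times, lfp, window=50.0)
    end_env = float(env[times >= total - 200.0].max()) if direction == "up" else float(
        env[times <= baseline + 200.0].max()
    )
    onset_time = float("nan")
    thresh = onset_fraction * end_env
    if end_env > 1e-4:
        above = np.where(env >= thresh)[0]
        if len(above):
            onset_time = float(times[above[0]] if direction == "up" else times[above[-1]])

    try:
        je_star = static_critical_current(base_params, beta, (0.0, J_e_end))
        je_t_arr = je_of_t(times)
        crossing = np.where(
            (je_t_arr[:-1] - je_star) * (je_t_arr[1:] - je_star) <= 0
        )[0]
        static_time = float(times[crossing[0] + 1]) if len(crossing) else float("nan")
    except ConfigurationError:
        je_star, static_time = float("nan"), float("nan")

    return RampResult(
        times=times, J_e=je_of_t(times), J_i=ji_of_t(times), lfp=lfp,
        envelope=env, onset_time=onset_time, static_onset_time=static_time,
        static_J_e=je_star, direction=direction, beta=beta,
    )


def spectrogram_db(
    signal: np.ndarray,
    sample_rate: float,
    window: float = 256.0,
    overlap: float = 0.75,
    baseline: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power in dB, baseline-subtracted per frequency band.

    ``window`` in ms (Hann), ``baseline`` an interval in ms over the
    returned time axis whose mean dB power is subtracted from every band.
    Returns ``(times_ms, freqs_hz, power_db)`` with power shaped
    (freq, time).
    """
    from scipy.signal import spectrogram as _spectrogram

    nperseg = int(round(window * sample_rate / 1000.0))
    if nperseg > len(signal):
        raise ConfigurationError("signal shorter than one spectrogram window")
    noverlap = int(round(overlap * nperseg))
    f, t, sxx = _spectrogram(np.asarray(signal, float), fs=sample_rate,
                             window="hann", nperseg=nperseg, noverlap=noverlap,
                             scaling="density", mode="psd")
    t_ms = t * 1000.0
    db = 10.0 * np.log10(sxx + 1e-300)
    if baseline is not None:
        b0, b1 = baseline
        sel = (t_ms >= b0) & (t_ms <= b1)
        if sel.sum() < 1:
            raise ConfigurationError("baseline interval shorter than one window")
        db = db - db[:, sel].mean(axis=1, keepdims=True)
    return t_ms, f, db
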