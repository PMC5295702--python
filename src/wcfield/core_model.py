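"""Isolated excitatory-inhibitory Wilson-Cowan pair.

The local circuit is a pair of coupled firing-rate equations

    tau_e dUe/dt = -Ue + F(k_ee*Ue - k_ei*Ui + J_e - b_e)
    tau_i dUi/dt = -Ui + F(k_ie*Ue - k_ii*Ui + J_i - b_i)

where ``F`` is the logistic sigmoid, ``b_e``/``b_i`` are firing thresholds,
``J_e``/``J_i`` are external (e.g. optogenetically induced) currents and the
``k_xy`` are connection weights.  The local field potential is modelled as the
weighted sum ``LFP = 0.8*Ue + 0.2*Ui``, reflecting the dominance of pyramidal
dipoles in the extracellular field.

This module integrates the pair with a fixed-step classical Runge-Kutta
scheme, locates all fixed points in the unit square, linearises around them,
and measures the frequency and envelope of limit-cycle oscillations.  All
state-evolving functions broadcast over NumPy arrays in the parameter fields,
which is how the bifurcation sweeps vectorise whole parameter grids into a
single integration pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.optimize import root as _scipy_root
from scipy.signal import find_peaks
from scipy.special import expit

__all__ = [
    "ConfigurationError",
    "UndersampledError",
    "PointParams",
    "FixedPoint",
    "PointTrajectory",
    "OscillationMeasure",
    "TYPE_II_PARAMS",
    "TYPE_I_PARAMS",
    "LFP_WEIGHT_E",
    "LFP_WEIGHT_I",
    "sigmoid",
    "sigmoid_prime",
    "lfp_of",
    "point_derivatives",
    "simulate_point",
    "find_fixed_points",
    "jacobian",
    "jacobian_eigenvalues",
    "measure_oscillation",
]

#: LFP mixing weights: excitatory cells contribute four times the inhibitory
#: weight (dipole geometry and prevalence).
LFP_WEIGHT_E = 0.8
LFP_WEIGHT_I = 0.2


class ConfigurationError(ValueError):
    """A parameter combination violates a model or solver constraint."""


class UndersampledError(RuntimeError):
    """A trajectory is too short to measure the requested quantity."""


@dataclass(frozen=True)
class PointParams:
    """Parameters of the isolated excitatory-inhibitory pair.

    Defaults are the standard configuration of the model: with ``b_i = 4``
    the pair is type II excitable (supercritical Hopf onset); raising the
    inhibitory threshold to ``b_i = 8`` shifts the inhibitory nullcline onto
    the middle branch of the excitatory nullcline and yields type I (SNIC)
    excitability.

    Weights and thresholds are dimensionless, time constants in ms.
    Any field may be a NumPy array for vectorised parameter sweeps.
    """

    k_ee: float = 15.0
    k_ei: float = 15.0
    k_ie: float = 15.0
    k_ii: float = 7.0
    b_e: float = 4.0
    b_i: float = 4.0
    tau_e: float = 2.0  # ms
    tau_i: float = 4.0  # ms
    J_e: float = 0.0
    J_i: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tau_e) <= 0) or np.any(np.asarray(self.tau_i) <= 0):
            raise ConfigurationError("time constants must be positive")
        for name in ("k_ee", "k_ei", "k_ie", "k_ii"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ConfigurationError(f"connection weight {name} must be >= 0")

    def replace(self, **changes) -> "PointParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_toml(self, section: str = "point") -> str:
        lines = [f"[{section}]"]
        lines += [f"{k} = {float(v)!r}" for k, v in self.as_dict().items()]
        return "\n".join(lines) + "\n"


#: Type II excitable defaults (supercritical Hopf under J_e injection).
TYPE_II_PARAMS = PointParams()
#: Type I excitable variant (SNIC onset; only the inhibitory threshold moves).
TYPE_I_PARAMS = PointParams(b_i=8.0)


def sigmoid(u):
    """Logistic firing-rate function ``F(u) = 1/(1+exp(-u))``.

    Overflow-safe for arbitrarily large ``|u|``; rejects non-finite input.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("sigmoid input must be finite")
    out = expit(u)
    return out if out.ndim else float(out)


def sigmoid_prime(u):
    """Derivative of the logistic sigmoid, ``F'(u) = F(u)(1-F(u))``."""
    f = expit(np.asarray(u, dtype=float))
    return f * (1.0 - f)


def lfp_of(U_e, U_i):
    """Local field potential proxy ``0.8*Ue + 0.2*Ui``."""
    return LFP_WEIGHT_E * np.asarray(U_e) + LFP_WEIGHT_I * np.asarray(U_i)


def point_derivatives(state, params: PointParams):
    """Right-hand side of the pair equations at ``state = (Ue, Ui)``.

    Returns ``(dUe/dt, dUi/dt)`` in 1/ms.  Broadcasts over arrays.
    """
    U_e, U_i = np.asarray(state[0], float), np.asarray(state[1], float)
    if not (np.all(np.isfinite(U_e)) and np.all(np.isfinite(U_i))):
        raise ValueError("state components must be finite")
    drive_e = params.k_ee * U_e - params.k_ei * U_i + params.J_e - params.b_e
    drive_i = params.k_ie * U_e - params.k_ii * U_i + params.J_i - params.b_i
    dUe = (-U_e + expit(drive_e)) / params.tau_e
    dUi = (-U_i + expit(drive_i)) / params.tau_i
    return dUe, dUi


@dataclass
class PointTrajectory:
    """Uniformly sampled time series of the pair.

    ``U_e``/``U_i`` have shape ``(n_times,) + batch_shape`` when the
    parameters carried array-valued fields.
    """

    times: np.ndarray  # ms
    U_e: np.ndarray
    U_i: np.ndarray
    params: PointParams

    @property
    def lfp(self) -> np.ndarray:
        return lfp_of(self.U_e, self.U_i)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_dataframe(self):
        import pandas as pd

        if self.U_e.ndim != 1:
            raise ValueError("to_dataframe requires a non-batched trajectory")
        return pd.DataFrame(
            {"time_ms": self.times, "Ue": self.U_e, "Ui": self.U_i, "LFP": self.lfp}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path_or_group, group: str = "point") -> None:
        import h5py

        def _write(g):
            g.create_dataset("times_ms", data=self.times)
            g.create_dataset("Ue", data=self.U_e)
            g.create_dataset("Ui", data=self.U_i)
            g.create_dataset("LFP", data=self.lfp)
            for k, v in self.params.as_dict().items():
                g.attrs[k] = v

        if isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__"):
            with h5py.File(path_or_group, "w") as f:
                _write(f.create_group(group))
        else:
            _write(path_or_group)


def _rk4_step(U_e, U_i, params: PointParams, dt: float):
    k1e, k1i = point_derivatives((U_e, U_i), params)
    k2e, k2i = point_derivatives((U_e + 0.5 * dt * k1e, U_i + 0.5 * dt * k1i), params)
    k3e, k3i = point_derivatives((U_e + 0.5 * dt * k2e, U_i + 0.5 * dt * k2i), params)
    k4e, k4i = point_derivatives((U_e + dt * k3e, U_i + dt * k3i), params)
    U_e = U_e + (dt / 6.0) * (k1e + 2 * k2e + 2 * k3e + k4e)
    U_i = U_i + (dt / 6.0) * (k1i + 2 * k2i + 2 * k3i + k4i)
    return U_e, U_i


def simulate_point(
    params: PointParams,
    init: Sequence[float] = (0.0, 0.0),
    duration: float = 500.0,
    dt: float = 0.01,
    store_every: int = 1,
) -> PointTrajectory:
    """Integrate the pair with fixed-step classical RK4.

    Parameters
    ----------
    params:
        Model parameters; array-valued fields run a whole batch at once.
    init:
        Initial ``(Ue, Ui)``; broadcast against the parameter batch shape.
    duration, dt:
        Total time and step, both ms.  ``dt`` must satisfy the stability
        guard ``dt <= min(tau_e, tau_i)/10``.
    store_every:
        Keep every ``store_every``-th sample (the initial state is always
        stored).
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    tau_min = min(np.min(np.asarray(params.tau_e)), np.min(np.asarray(params.tau_i)))
    if dt > tau_min / 10.0 + 1e-12:
        raise ConfigurationError(
            f"dt={dt} too large for smallest time constant {tau_min} ms "
            "(require dt <= tau/10)"
        )
    n_steps = int(round(duration / dt))
    batch = np.broadcast_shapes(
        *(np.asarray(v).shape for v in params.as_dict().values()),
        np.asarray(init[0]).shape,
        np.asarray(init[1]).shape,
    )
    U_e = np.broadcast_to(np.asarray(init[0], float), batch).copy()
    U_i = np.broadcast_to(np.asarray(init[1], float), batch).copy()

    stored_idx = list(range(0, n_steps + 1, store_every))
    out_e = np.empty((len(stored_idx),) + batch)
    out_i = np.empty_like(out_e)
    out_e[0], out_i[0] = U_e, U_i
    j = 1
    for step in range(1, n_steps + 1):
        U_e, U_i = _rk4_step(U_e, U_i, params, dt)
        if j < len(stored_idx) and step == stored_idx[j]:
            out_e[j], out_i[j] = U_e, U_i
            j += 1
    times = np.asarray(stored_idx, float) * dt
    if not batch:
        out_e, out_i = out_e.reshape(-1), out_i.reshape(-1)
    return PointTrajectory(times=times, U_e=out_e, U_i=out_i, params=params)


@dataclass(frozen=True)
class FixedPoint:
    """A root of the pair equations with its linearisation."""

    U_e: float
    U_i: float
    eigenvalues: tuple  # two complex numbers, 1/ms
    stable: bool

    @property
    def state(self) -> tuple:
        return (self.U_e, self.U_i)


def jacobian(params: PointParams, state) -> np.ndarray:
    """Analytic 2x2 Jacobian of the pair equations at ``state``."""
    U_e, U_i = state
    a = params.k_ee * U_e - params.k_ei * U_i + params.J_e - params.b_e
    b = params.k_ie * U_e - params.k_ii * U_i + params.J_i - params.b_i
    fa, fb = sigmoid_prime(a), sigmoid_prime(b)
    return np.array(
        [
            [(-1.0 + fa * params.k_ee) / params.tau_e, (-fa * params.k_ei) / params.tau_e],
            [(fb * params.k_ie) / params.tau_i, (-1.0 - fb * params.k_ii) / params.tau_i],
        ]
    )


def _residual(state, params: PointParams):
    d = point_derivatives(state, params)
    return np.array([d[0], d[1]])


def jacobian_eigenvalues(params: PointParams, fp_state, residual_tol: float = 1e-8):
    """Eigenvalues (1/ms) of the linearisation at a fixed point.

    Raises if ``fp_state`` is not actually a fixed point to ``residual_tol``.
    """
    res = np.linalg.norm(_residual(fp_state, params))
    if res > residual_tol:
        raise ValueError(f"state is not a fixed point (residual {res:.2e} > {residual_tol:.0e})")
    return tuple(np.linalg.eigvals(jacobian(params, fp_state)))


def find_fixed_points(
    params: PointParams,
    n_seeds: int = 11,
    dedup_tol: float = 1e-4,
    residual_tol: float = 1e-10,
) -> list[FixedPoint]:
    """All fixed points in the unit square, with stability.

    Multi-start root finding from an ``n_seeds`` x ``n_seeds`` uniform grid
    over (0,1)^2; the bounded sigmoid guarantees at least one root.  Roots
    closer than ``dedup_tol`` (Euclidean) are merged.
    """
    seeds = np.linspace(0.0, 1.0, n_seeds)
    roots: list[np.ndarray] = []
    for se in seeds:
        for si in seeds:
            sol = _scipy_root(
                _residual,
                x0=np.array([se, si]),
                args=(params,),
                jac=lambda s, p: jacobian(p, s),
                method="hybr",
                tol=1e-12,
            )
            if not sol.success:
                continue
            x = sol.x
            if np.linalg.norm(_residual(x, params)) > residual_tol:
                continue
            if not (-1e-9 <= x[0] <= 1 + 1e-9 and -1e-9 <= x[1] <= 1 + 1e-9):
                continue
            if not any(np.linalg.norm(x - r) < dedup_tol for r in roots):
                roots.append(x)
    out = []
    for r in sorted(roots, key=lambda r: (r[0], r[1])):
        eig = tuple(np.linalg.eigvals(jacobian(params, r)))
        out.append(
            FixedPoint(
                U_e=float(r[0]),
                U_i=float(r[1]),
                eigenvalues=eig,
                stable=bool(max(e.real for e in eig) < 0),
            )
        )
    return out


@dataclass(frozen=True)
class OscillationMeasure:
    """Frequency and post-transient envelope of a trajectory.

    ``frequency_hz`` is ``nan`` for non-oscillating input (peak-to-peak LFP
    amplitude below ``amp_threshold`` after the transient discard).
    """

    frequency_hz: float
    amplitude: float  # peak-to-peak LFP
    U_e_min: float
    U_e_max: float
    lfp_min: float
    lfp_max: float

    @property
    def oscillating(self) -> bool:
        return np.isfinite(self.frequency_hz)


def measure_oscillation(
    traj: PointTrajectory | tuple,
    discard: float = 200.0,
    amp_threshold: float = 1e-4,
) -> OscillationMeasure:
    """Oscillation frequency and envelope after discarding a transient.

    Frequency is the reciprocal of the mean inter-peak interval of the LFP.
    Accepts a :class:`PointTrajectory` or a ``(times_ms, lfp)`` pair (in the
    latter case the U_e envelope fields repeat the LFP envelope).
    """
    if isinstance(traj, PointTrajectory):
        times, sig, ue = traj.times, np.asarray(traj.lfp), np.asarray(traj.U_e)
    else:
        times, sig = np.asarray(traj[0], float), np.asarray(traj[1], float)
        ue = sig
    keep = times >= discard
    if keep.sum() < 8:
        raise UndersampledError("trajectory shorter than the transient discard")
    t, s, u = times[keep], sig[keep], ue[keep]
    amp = float(s.max() - s.min())
    env = dict(
        U_e_min=float(u.min()),
        U_e_max=float(u.max()),
        lfp_min=float(s.min()),
        lfp_max=float(s.max()),
    )
    if amp < amp_threshold:
        return OscillationMeasure(frequency_hz=float("nan"), amplitude=0.0, **env)
    peaks, _ = find_peaks(s, prominence=0.1 * amp)
    if len(peaks) < 3:
        raise UndersampledError(
            f"only {len(peaks)} LFP peaks after the transient; lengthen the run"
        )
    period_ms = float(np.mean(np.diff(t[peaks])))
    return OscillationMeasure(frequency_hz=1000.0 / period_ms, amplitude=amp, **env)
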