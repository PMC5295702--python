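"""1D continuum Wilson-Cowan neural field.

A 6 mm strip of cortex (default half-length 3 mm) is discretised into a
chain of excitatory-inhibitory pairs coupled through Gaussian kernels

    K_xy(x) = (k_xy / (sigma sqrt(pi))) * exp(-x^2 / sigma^2)

whose integral over space equals the connection mass ``k_xy``.  Projections
from excitatory populations reach twice as far as inhibitory ones
(sigma_e = 2 sigma_i by default).  Focal optogenetic stimulation is a square
current profile (0.4 mm wide) applied at the centre of the chain, optionally
scaled in time by a piecewise-linear ramp schedule.

Boundaries are absorbing: within a sponge layer at each end an extra
relaxation term -lambda(x) (U - U_rest) pulls the field back to rest, with
lambda ramping linearly from 0 at the inner edge of the layer to
``SPONGE_RATE_MAX`` at the wall.  This removes outgoing wave energy without
disturbing the interior.  A periodic mode exists for validation against the
point model.

Integration is fixed-step classical RK4.  The time stepper operates on a
``(batch, n_nodes)`` state so that parameter sweeps (different time
constants or stimulus amplitudes on a shared grid and kernels) run as a
single vectorised pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from wcfield.core_model import (
    ConfigurationError,
    PointParams,
    find_fixed_points,
    lfp_of,
)

__all__ = [
    "FieldParams",
    "StimulusSpec",
    "FieldTrajectory",
    "SPONGE_RATE_MAX",
    "make_kernel",
    "convolve_field",
    "convolve_field_direct",
    "rest_state",
    "simulate_field",
    "simulate_field_batch",
]

#: Peak relaxation rate (1/ms) at the outer edge of the absorbing layer.
SPONGE_RATE_MAX = 5.0


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the spatially extended model.

    The connection weights are now kernel masses (integrals of the Gaussian
    profiles); everything else matches :class:`~wcfield.core_model.PointParams`.
    ``J_e``/``J_i`` here are spatially uniform background currents (usually
    zero); focal stimulation is specified separately via
    :class:`StimulusSpec`.
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
    sigma_e: float = 0.2  # mm
    sigma_i: float = 0.1  # mm
    dx: float = 0.01  # mm
    half_length: float = 3.0  # mm
    sponge_width: float = 0.4  # mm

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ConfigurationError("kernel spreads must be positive")
        if self.dx <= 0:
            raise ConfigurationError("dx must be positive")
        if self.dx > min(self.sigma_e, self.sigma_i) / 5.0 + 1e-12:
            raise ConfigurationError(
                f"dx={self.dx} too coarse for kernel spread "
                f"{min(self.sigma_e, self.sigma_i)} mm (require dx <= sigma/5)"
            )
        if abs(self.sigma_e - 2.0 * self.sigma_i) > 1e-9:
            warnings.warn(
                "excitatory kernels usually spread twice as far as inhibitory "
                f"ones; got sigma_e={self.sigma_e}, sigma_i={self.sigma_i}",
                stacklevel=3,
            )

    def replace(self, **changes) -> "FieldParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_toml(self, section: str = "field") -> str:
        lines = [f"[{section}]"]
        lines += [f"{k} = {float(v)!r}" for k, v in self.as_dict().items()]
        return "\n".join(lines) + "\n"

    def point(self, **overrides) -> PointParams:
        """The equivalent isolated pair (kernel masses as scalar weights)."""
        keep = {f.name for f in fields(PointParams)}
        d = {k: v for k, v in self.as_dict().items() if k in keep}
        d.update(overrides)
        return PointParams(**d)

    @property
    def grid(self) -> np.ndarray:
        n = int(round(2 * self.half_length / self.dx)) + 1
        return np.linspace(-self.half_length, self.half_length, n)


@dataclass(frozen=True)
class StimulusSpec:
    """Focal square-profile current source.

    ``ramp`` is a list of ``(time_ms, scale)`` breakpoints, linearly
    interpolated and held constant beyond the last breakpoint; the default
    is steady stimulation at full amplitude from t = 0.  ``ramp_i``, when
    given, schedules the inhibitory amplitude independently (needed when
    J_i follows a nonlinear recruitment law rather than scaling with J_e).
    """

    center: float = 0.0  # mm
    width: float = 0.4  # mm
    J_e: float = 0.0
    J_i: float = 0.0
    ramp: tuple = ((0.0, 1.0),)
    ramp_i: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("stimulus width must be positive")
        for sched in (self.ramp, self.ramp_i or ()):
            if any(s < 0 for _, s in sched):
                raise ConfigurationError("ramp scale factors must be >= 0")

    def replace(self, **changes) -> "StimulusSpec":
        return replace(self, **changes)

    def mask(self, grid: np.ndarray) -> np.ndarray:
        return (np.abs(grid - self.center) <= self.width / 2.0 + 1e-12).astype(float)

    def scale_at(self, t_ms: float) -> float:
        tp = np.array([b[0] for b in self.ramp])
        sp = np.array([b[1] for b in self.ramp])
        return float(np.interp(t_ms, tp, sp))


def make_kernel(sigma: float, k: float, dx: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian coupling kernel sampled on the dx grid.

    Returns an odd-length symmetric array of ``(k/(sigma sqrt(pi)))
    exp(-x^2/sigma^2)`` out to ``truncate * sigma``; its Riemann sum times
    ``dx`` recovers the mass ``k`` to well under 0.1 %.
    """
    if truncate < 4.0:
        raise ConfigurationError("kernel truncation half-width must be >= 4 sigma")
    if dx > sigma / 5.0 + 1e-12:
        raise ConfigurationError(f"dx={dx} too coarse for sigma={sigma} (require dx <= sigma/5)")
    m = int(np.ceil(truncate * sigma / dx))
    x = np.arange(-m, m + 1) * dx
    return (k / (sigma * np.sqrt(np.pi))) * np.exp(-(x**2) / sigma**2)


def convolve_field(kernel: np.ndarray, values: np.ndarray, dx: float,
                   pad_value: float = 0.0, periodic: bool = False) -> np.ndarray:
    """Spatial convolution of a field with a coupling kernel.

    ``values`` may be ``(n,)`` or ``(batch, n)``; convolution acts along the
    last axis with no wrap-around (ends padded with ``pad_value``, normally
    the resting rate, so the boundary sees a field at rest rather than an
    artificial void).  The result is scaled by ``dx`` to approximate the
    continuum integral.
    """
    values = np.asarray(values, float)
    mode = "wrap" if periodic else "constant"
    return convolve1d(values, kernel, axis=-1, mode=mode, cval=pad_value) * dx


def convolve_field_direct(kernel: np.ndarray, values: np.ndarray, dx: float,
                          pad_value: float = 0.0) -> np.ndarray:
    """O(N*M) summation reference for :func:`convolve_field` (test oracle)."""
    values = np.asarray(values, float)
    m = len(kernel) // 2
    out = np.empty_like(values, dtype=float)
    for i in range(values.shape[-1]):
        acc = 0.0
        for j, kj in enumerate(kernel):
            idx = i + (j - m)
            v = values[..., idx] if 0 <= idx < values.shape[-1] else pad_value
            acc = acc + kj * v
        out[..., i] = acc
    return out * dx


def rest_state(params: FieldParams) -> tuple[float, float]:
    """Homogeneous resting state: the stable fixed point of the local pair."""
    fps = find_fixed_points(params.point())
    stable = [f for f in fps if f.stable]
    if not stable:
        raise ConfigurationError("local dynamics have no stable rest state")
    low = min(stable, key=lambda f: f.U_e)
    return (low.U_e, low.U_i)


@dataclass
class FieldTrajectory:
    """Stored space-time simulation output (times x space arrays)."""

    grid: np.ndarray  # mm
    times: np.ndarray  # ms
    U_e: np.ndarray  # (n_times, n_nodes)
    U_i: np.ndarray
    params: FieldParams
    stim: Optional[StimulusSpec] = None

    @property
    def lfp(self) -> np.ndarray:
        return lfp_of(self.U_e, self.U_i)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("grid_mm", data=self.grid)
            f.create_dataset("times_ms", data=self.times)
            f.create_dataset("Ue", data=self.U_e)
            f.create_dataset("Ui", data=self.U_i)
            f.create_dataset("LFP", data=self.lfp)
            for k, v in self.params.as_dict().items():
                f.attrs[k] = v
            if self.stim is not None:
                f.attrs["stim_center_mm"] = self.stim.center
                f.attrs["stim_width_mm"] = self.stim.width
                f.attrs["stim_J_e"] = self.stim.J_e
                f.attrs["stim_J_i"] = self.stim.J_i

    def render(self, path, cmap: str = "viridis") -> None:
        """Space-time LFP plot to PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(self.grid, self.times, self.lfp, cmap=cmap, shading="auto")
        ax.set_xlabel("space (mm)")
        ax.set_ylabel("time (ms)")
        fig.colorbar(im, ax=ax, label="LFP")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _sponge_profile(params: FieldParams) -> np.ndarray:
    """Relaxation rate lambda(x), linear 0 -> SPONGE_RATE_MAX in each layer."""
    x = params.grid
    lam = np.zeros_like(x)
    w = params.sponge_width
    if w > 0:
        depth = np.maximum(0.0, np.abs(x) - (params.half_length - w)) / w
        lam = SPONGE_RATE_MAX * depth
    return lam


def simulate_field_batch(
    params: FieldParams,
    stim: StimulusSpec,
    duration: float,
    dt: float = 0.01,
    store_every: int = 50,
    tau_e: Optional[Sequence[float]] = None,
    tau_i: Optional[Sequence[float]] = None,
    stim_J_e: Optional[Sequence[float]] = None,
    stim_J_i: Optional[Sequence[float]] = None,
    boundary: str = "sponge",
) -> list[FieldTrajectory]:
    """Integrate a batch of field simulations sharing grid and kernels.

    The optional per-batch overrides (``tau_e``, ``tau_i``, ``stim_J_e``,
    ``stim_J_i``) must broadcast to a common batch length; kernels and the
    spatial grid are shared, which is what makes the batch worthwhile.
    Returns one :class:`FieldTrajectory` per batch element.
    """
    if boundary not in ("sponge", "periodic"):
        raise ConfigurationError(f"unknown boundary mode {boundary!r}")
    overrides = [np.atleast_1d(np.asarray(v, float))
                 for v in (tau_e, tau_i, stim_J_e, stim_J_i) if v is not None]
    B = int(np.broadcast_shapes(*(o.shape for o in overrides), (1,))[0]) if overrides else 1
    te = np.broadcast_to(np.atleast_1d(tau_e if tau_e is not None else params.tau_e), (B,))
    ti = np.broadcast_to(np.atleast_1d(tau_i if tau_i is not None else params.tau_i), (B,))
    je_amp = np.broadcast_to(np.atleast_1d(stim_J_e if stim_J_e is not None else stim.J_e), (B,))
    ji_amp = np.broadcast_to(np.atleast_1d(stim_J_i if stim_J_i is not None else stim.J_i), (B,))
    tau_min = min(te.min(), ti.min())
    if dt > tau_min / 10.0 + 1e-12:
        raise ConfigurationError(
            f"dt={dt} too large for smallest time constant {tau_min} ms"
        )
    if boundary == "sponge" and params.half_length <= stim.width / 2.0:
        raise ConfigurationError("domain half-length must exceed the stimulus half-width")

    x = params.grid
    n = len(x)
    ker_e = make_kernel(params.sigma_e, 1.0, params.dx)  # unit-mass kernels
    ker_i = make_kernel(params.sigma_i, 1.0, params.dx)
    ue_rest, ui_rest = rest_state(params)
    periodic = boundary == "periodic"
    lam = _sponge_profile(params) if boundary == "sponge" else np.zeros(n)

    mask = stim.mask(x)  # (n,)
    je_x = je_amp[:, None] * mask[None, :] + params.J_e  # (B, n)
    ji_x = ji_amp[:, None] * mask[None, :] + params.J_i
    te_c = te[:, None]
    ti_c = ti[:, None]

    from scipy.special import expit

    def rhs(Ue, Ui, scale, scale_i):
        Ce = convolve_field(ker_e, Ue, params.dx, pad_value=ue_rest, periodic=periodic)
        Ci = convolve_field(ker_i, Ui, params.dx, pad_value=ui_rest, periodic=periodic)
        drive_e = params.k_ee * Ce - params.k_ei * Ci + scale * je_x - params.b_e
        drive_i = params.k_ie * Ce - params.k_ii * Ci + scale_i * ji_x - params.b_i
        dUe = (-Ue + expit(drive_e)) / te_c - lam * (Ue - ue_rest)
        dUi = (-Ui + expit(drive_i)) / ti_c - lam * (Ui - ui_rest)
        return dUe, dUi

    n_steps = int(round(duration / dt))
    Ue = np.full((B, n), ue_rest)
    Ui = np.full((B, n), ui_rest)
    stored = list(range(0, n_steps + 1, store_every))
    out_e = np.empty((len(stored), B, n))
    out_i = np.empty_like(out_e)
    out_e[0], out_i[0] = Ue, Ui
    j = 1
    # precompute the ramp scales at stage times
    tgrid = np.arange(n_steps + 1) * dt
    ramp_i = stim.ramp_i if stim.ramp_i is not None else stim.ramp

    def _interp(sched, t):
        return np.interp(t, [b[0] for b in sched], [b[1] for b in sched])

    scale_full = _interp(stim.ramp, tgrid)
    scale_half = _interp(stim.ramp, tgrid[:-1] + 0.5 * dt)
    scale_i_full = _interp(ramp_i, tgrid)
    scale_i_half = _interp(ramp_i, tgrid[:-1] + 0.5 * dt)
    for step in range(n_steps):
        s0, sh, s1 = scale_full[step], scale_half[step], scale_full[step + 1]
        q0, qh, q1 = scale_i_full[step], scale_i_half[step], scale_i_full[step + 1]
        k1e, k1i = rhs(Ue, Ui, s0, q0)
        k2e, k2i = rhs(Ue + 0.5 * dt * k1e, Ui + 0.5 * dt * k1i, sh, qh)
        k3e, k3i = rhs(Ue + 0.5 * dt * k2e, Ui + 0.5 * dt * k2i, sh, qh)
        k4e, k4i = rhs(Ue + dt * k3e, Ui + dt * k3i, s1, q1)
        Ue = Ue + (dt / 6.0) * (k1e + 2 * k2e + 2 * k3e + k4e)
        Ui = Ui + (dt / 6.0) * (k1i + 2 * k2i + 2 * k3i + k4i)
        if j < len(stored) and step + 1 == stored[j]:
            if not np.all(np.isfinite(Ue)):
                bad = np.argwhere(~np.isfinite(Ue))[0]
                raise FloatingPointError(
                    f"field integration diverged at t={(step+1)*dt:.3f} ms, "
                    f"batch {bad[0]}, x={x[bad[1]]:.3f} mm"
                )
            out_e[j], out_i[j] = Ue, Ui
            j += 1
    times = np.asarray(stored, float) * dt
    trajs = []
    for b in range(B):
        p_b = params.replace(tau_e=float(te[b]), tau_i=float(ti[b]))
        s_b = stim.replace(J_e=float(je_amp[b]), J_i=float(ji_amp[b]))
        trajs.append(
            FieldTrajectory(grid=x, times=times, U_e=out_e[:, b], U_i=out_i[:, b],
                            params=p_b, stim=s_b)
        )
    return trajs


def simulate_field(
    params: FieldParams,
    stim: StimulusSpec,
    duration: float,
    dt: float = 0.01,
    store_every: int = 50,
    boundary: str = "sponge",
) -> FieldTrajectory:
    """Single field simulation (see :func:`simulate_field_batch`)."""
    return simulate_field_batch(params, stim, duration, dt=dt,
                                store_every=store_every, boundary=boundary)[0]
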