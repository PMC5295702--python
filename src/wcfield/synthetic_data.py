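"""Synthetic multielectrode LFP recordings with known ground truth.

Emulates the statistical structure of the in vivo array data the
re-analysis pipeline was built for: a localized high-frequency oscillation
(~100 Hz) at the stimulation source that emits an outward-travelling
wavefront on every n-th cycle (n:1 beat skipping), waves propagating at a
fixed radial speed with exponential spatial decay, plus pink (1/f) and
white measurement noise.  The original recordings were never deposited, so
these generated records are the test bed with exact ground truth for the
skip factor, wave speed and source frequency.

Every draw is fully determined by ``SynthSpec.seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from wcfield.core_model import ConfigurationError
from wcfield.reanalysis import ArrayRecording

__all__ = ["SynthSpec", "generate_array_recording"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings for one synthetic array recording.

    Defaults emulate the study conditions: a 10 x 10 grid at 0.4 mm pitch
    (4 x 4 mm^2 footprint), a 100 Hz source emitting a wave every 2nd cycle
    (so ~50 Hz waves) at 18.9 cm/s.
    """

    n_x: int = 10
    n_y: int = 10
    pitch: float = 0.4  # mm
    source: Optional[tuple] = None  # mm; default: array centre
    f_src: float = 100.0  # Hz
    n_skip: int = 2  # a wavefront leaves on every n-th source cycle
    speed_cm_s: float = 18.9
    decay_mm: float = 1.5  # exponential decay length of the wave amplitude
    source_decay_mm: float = 0.5  # spatial footprint of the source oscillation
    wave_amp: float = 1.0
    source_amp: float = 1.2
    pink_amp: float = 0.0  # RMS as a fraction of the wave-component RMS
    white_sd: float = 0.0  # absolute SD
    duration_s: float = 2.0
    fs: float = 2000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_skip < 1:
            raise ConfigurationError("n_skip must be >= 1")
        if self.speed_cm_s <= 0:
            raise ConfigurationError("wave speed must be positive")
        if self.duration_s * self.f_src / self.n_skip < 4:
            raise ConfigurationError("duration too short to hold any wavefronts")

    def replace(self, **changes) -> "SynthSpec":
        from dataclasses import replace

        return replace(self, **changes)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS pink noise via 1/sqrt(f) spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec = spec / np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _wave_pulse(tau: np.ndarray, f_wave: float) -> np.ndarray:
    """One sinusoidal cycle at ``f_wave`` under a raised-cosine window.

    ``tau`` is time since the front's arrival (s); zero outside one period.
    """
    period = 1.0 / f_wave
    inside = (tau >= 0) & (tau < period)
    out = np.zeros_like(tau)
    tt = tau[inside]
    out[inside] = np.sin(2 * np.pi * f_wave * tt) * 0.5 * (1 - np.cos(2 * np.pi * tt / period))
    return out


def generate_array_recording(spec: SynthSpec) -> tuple[ArrayRecording, dict]:
    """Build one synthetic recording plus its ground-truth record.

    The source channel carries ``f_src``; wavefronts at ``f_src/n_skip``
    leave the source phase-locked to every ``n_skip``-th source cycle and
    arrive at radius r after ``r / speed``, with amplitude
    ``wave_amp * exp(-r/decay_mm)``.  Additive pink noise is calibrated to
    ``pink_amp`` times the RMS of the wave component; white noise has
    absolute SD ``white_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    xs = np.arange(spec.n_x) * spec.pitch
    ys = np.arange(spec.n_y) * spec.pitch
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    source = (
        np.asarray(spec.source, float)
        if spec.source is not None
        else np.array([xs.mean(), ys.mean()])
    )
    r = np.linalg.norm(coords - source, axis=1)

    n_t = int(round(spec.duration_s * spec.fs))
    t = np.arange(n_t) / spec.fs  # s
    v_mm_s = spec.speed_cm_s * 10.0
    f_wave = spec.f_src / spec.n_skip
    emit_times = np.arange(0.0, spec.duration_s + 1.0 / f_wave, 1.0 / f_wave)

    lfp = np.empty((len(coords), n_t))
    wave_rms_acc = 0.0
    for c in range(len(coords)):
        wave = np.zeros(n_t)
        arrival_delay = r[c] / v_mm_s
        for t0 in emit_times:
            wave += _wave_pulse(t - (t0 + arrival_delay), f_wave)
        wave *= spec.wave_amp * np.exp(-r[c] / spec.decay_mm)
        src = spec.source_amp * np.exp(-r[c] / spec.source_decay_mm) * np.sin(
            2 * np.pi * spec.f_src * t
        )
        lfp[c] = wave + src
        wave_rms_acc += float(np.mean(wave**2))
    wave_rms = np.sqrt(wave_rms_acc / len(coords))

    if spec.pink_amp > 0:
        for c in range(len(coords)):
            lfp[c] += spec.pink_amp * wave_rms * _pink_noise(rng, n_t)
    if spec.white_sd > 0:
        lfp += rng.normal(0.0, spec.white_sd, size=lfp.shape)

    rec = ArrayRecording(coords=coords, fs=spec.fs, lfp=lfp, source=source)
    truth = dict(asdict(spec), f_wave_hz=f_wave, wave_rms=wave_rms,
                 source_mm=tuple(source))
    return rec, truth
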