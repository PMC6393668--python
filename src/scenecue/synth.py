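"""Synthetic stand-ins for the study's speech and environmental recordings.

Two source classes are emulated:

* *speech-like* — broadband noise amplitude-modulated by a quasi-rhythmic
  positive modulator whose spectral energy is concentrated in the 4-8 Hz
  range, the band in which natural speech envelopes carry their prominent
  syllabic rhythm.  The modulator is a rectified sum of a few random-phase
  sinusoids plus a DC floor, so its ground truth is known analytically and
  envelope-recovery tests can compare against it.
* *environment-like* — a stationary noise texture whose coarse envelope is
  flat, mimicking the rather stationary analytic envelopes of ambient
  recordings (rain, traffic, crowds).

Both carriers are approximately pink (spectrum shaped as 1/sqrt(f)); all
outputs are deterministic given the seed and peak-guarded to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import AudioSegment

__all__ = ["SourceSpec", "synth_speechlike", "synth_envlike", "speechlike_modulator"]

_PEAK_GUARD = 0.9
_N_MOD_COMPONENTS = 4
_MOD_DC_FLOOR = 0.25


@dataclass(frozen=True)
class SourceSpec:
    """Parameters of one synthetic source realization."""

    kind: str  # "speechlike" | "envlike"
    duration: float
    seed: int
    rate: int = 44100
    mod_rate_range: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        if self.kind not in ("speechlike", "envlike"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        lo, hi = self.mod_rate_range
        if not lo < hi:
            raise ValueError(f"mod_rate_range must satisfy low < high, got {self.mod_rate_range}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximately pink (-3 dB/octave) noise via 1/sqrt(f) spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0  # no DC
    pink = np.fft.irfft(spectrum * shaping, n)
    return pink / np.max(np.abs(pink))


def speechlike_modulator(spec: SourceSpec) -> np.ndarray:
    """Ground-truth quasi-rhythmic modulator for a speech-like source.

    Rectified sum of ``_N_MOD_COMPONENTS`` sinusoids with frequencies drawn
    uniformly in ``spec.mod_rate_range`` and random phases, riding on a DC
    floor that keeps the modulator strictly positive often enough for the
    carrier's fine structure to survive everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.rate)
    t = np.arange(n) / spec.rate
    lo, hi = spec.mod_rate_range
    freqs = rng.uniform(lo, hi, size=_N_MOD_COMPONENTS)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_N_MOD_COMPONENTS)
    amps = rng.uniform(0.5, 1.0, size=_N_MOD_COMPONENTS)
    mixture = np.zeros(n)
    for f, p, a in zip(freqs, phases, amps):
        mixture += a * np.sin(2.0 * np.pi * f * t + p)
    return np.maximum(mixture, 0.0) + _MOD_DC_FLOOR


def synth_speechlike(spec: SourceSpec) -> AudioSegment:
    """Pink-noise carrier modulated by the quasi-rhythmic speech-like envelope."""
    if spec.kind != "speechlike":
        raise ValueError(f"spec.kind must be 'speechlike', got {spec.kind!r}")
    modulator = speechlike_modulator(spec)
    # Carrier drawn from an offset stream of the same seed so the modulator
    # alone can be regenerated independently for ground-truth comparisons.
    carrier_rng = np.random.default_rng(spec.seed + 2**20)
    carrier = _pink_noise(len(modulator), carrier_rng)
    x = carrier * modulator
    x *= _PEAK_GUARD / np.max(np.abs(x))
    return AudioSegment(samples=x, rate=spec.rate)


def synth_envlike(spec: SourceSpec) -> AudioSegment:
    """Stationary pink-noise texture with an (essentially) flat coarse envelope."""
    if spec.kind != "envlike":
        raise ValueError(f"spec.kind must be 'envlike', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.rate)
    x = _pink_noise(n, rng)
    x *= _PEAK_GUARD / np.max(np.abs(x))
    return AudioSegment(samples=x, rate=spec.rate)
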