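"""Audio container, WAV I/O, and source-preparation steps.

Sound sources are prepared for the repetition-detection task in three steps:
conversion to mono by channel averaging, cutting to a fixed duration (the
central part of the recording by default), and normalization to a fixed RMS
level of -23 dB re full scale.  All processing is done in floating point on
the nominal [-1, 1] amplitude scale; WAV files are written as 32-bit float
by default so that splice and envelope arithmetic survives a disk round trip
exactly, with an optional PCM16 export for player compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "StimulusConfig",
    "read_wav",
    "write_wav",
    "to_mono",
    "cut_segment",
    "normalize_rms",
    "rms_db",
]

#: RMS below which a signal is treated as silent / degenerate.
_SILENCE_RMS = 1e-12


class DegenerateSignalError(ValueError):
    """Raised when an operation receives an (effectively) all-zero signal."""


@dataclass(frozen=True)
class AudioSegment:
    """A sampled waveform with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude values on the nominal [-1, 1] scale.  Mono audio is a 1-D
        array of shape ``(n,)``; multi-channel audio is channel-major with
        shape ``(n_channels, n)``.
    rate : int
        Sampling rate in Hz.  Must be positive.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim not in (1, 2):
            raise ValueError(f"samples must be 1-D or 2-D, got shape {samples.shape}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class StimulusConfig:
    """Constants of the stimulus-construction pipeline.

    Defaults reproduce the published construction: 5-s scenes at 44.1 kHz,
    750-ms repetition epochs, 220-sample (5 ms) linear cross-fade ramps,
    envelope peaks separated by at least 4410 samples (0.1 s), and a stream
    level of -23 dB RMS re full scale.
    """

    sample_rate: int = 44100
    segment_duration: float = 5.0
    repetition_duration: float = 0.750
    ramp_samples: int = 220
    envelope_min_separation: int = 4410
    target_level_db: float = -23.0
    #: Targets never start or end closer than this to the stream edges.
    edge_margin: float = 0.250

    def __post_init__(self) -> None:
        rep_samples = self.repetition_duration * self.sample_rate
        if abs(rep_samples - round(rep_samples)) > 1e-9:
            raise ValueError(
                "repetition_duration x sample_rate must be an integer sample count, "
                f"got {rep_samples}"
            )
        if self.ramp_samples < 1:
            raise ValueError("ramp_samples must be >= 1")
        if self.envelope_min_separation < 1:
            raise ValueError("envelope_min_separation must be >= 1")
        if 2 * self.ramp_samples >= rep_samples:
            raise ValueError("repetition must be longer than two cross-fade ramps")

    @property
    def repetition_samples(self) -> int:
        return round(self.repetition_duration * self.sample_rate)

    @property
    def segment_samples(self) -> int:
        return round(self.segment_duration * self.sample_rate)

    @property
    def source_duration(self) -> float:
        """Duration sources must have before a repetition is embedded."""
        return self.segment_duration + self.repetition_duration


def read_wav(path: str | Path) -> AudioSegment:
    """Read a RIFF/WAVE file (PCM16 or IEEE float32) to the [-1, 1] scale.

    Multi-channel data is returned channel-major so that :func:`to_mono`
    can average across axis 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unsupported or corrupt WAV file {path}: {exc}") from exc
    except Exception as exc:  # scipy raises bare exceptions on truncated headers
        raise OSError(f"cannot read WAV file {path}: {exc}") from exc

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")

    if samples.ndim == 2:  # scipy returns frames x channels
        samples = samples.T
    return AudioSegment(samples=samples, rate=int(rate))


def write_wav(path: str | Path, audio: AudioSegment, *, pcm16: bool = False) -> None:
    """Write an :class:`AudioSegment`, float32 by default or PCM16 on request."""
    data = audio.samples.T if audio.samples.ndim == 2 else audio.samples
    if pcm16:
        clipped = np.clip(data, -1.0, 1.0 - 1.0 / 32768.0)
        wavfile.write(path, audio.rate, np.round(clipped * 32768.0).astype(np.int16))
    else:
        wavfile.write(path, audio.rate, data.astype(np.float32))


def to_mono(audio: AudioSegment) -> AudioSegment:
    """Average all channels to one, leaving mono input untouched."""
    if audio.samples.ndim == 1:
        return audio
    if audio.samples.shape[0] == 0:
        raise ValueError("cannot convert zero-channel audio to mono")
    return AudioSegment(samples=audio.samples.mean(axis=0), rate=audio.rate)


def cut_segment(
    audio: AudioSegment,
    duration: float,
    anchor: str = "center",
    offset: int = 0,
) -> AudioSegment:
    """Cut a fixed-duration window out of ``audio``, verbatim.

    ``anchor='center'`` takes the central window (ties broken toward the
    earlier start); ``'start'`` takes the window beginning at sample 0;
    ``'offset'`` begins at the given sample ``offset``.
    """
    n_out = round(duration * audio.rate)
    n_in = audio.n_samples
    if n_out > n_in:
        raise ValueError(
            f"requested duration {duration:.6f} s ({n_out} samples) exceeds "
            f"source duration {audio.duration_seconds:.6f} s ({n_in} samples)"
        )
    if anchor == "center":
        start = (n_in - n_out) // 2
    elif anchor == "start":
        start = 0
    elif anchor == "offset":
        start = int(offset)
        if start < 0 or start + n_out > n_in:
            raise ValueError(f"offset {start} puts the window outside the source")
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return AudioSegment(samples=audio.samples[..., start : start + n_out], rate=audio.rate)


def rms_db(audio: AudioSegment) -> float:
    """RMS level in dB re full scale (RMS of 1.0 -> 0 dB)."""
    rms = float(np.sqrt(np.mean(np.square(audio.samples))))
    if rms < _SILENCE_RMS:
        raise DegenerateSignalError("signal is silent; RMS level undefined")
    return 20.0 * np.log10(rms)


def normalize_rms(audio: AudioSegment, target_db: float = -23.0) -> AudioSegment:
    """Scale the signal so its RMS sits at ``target_db`` dB re full scale."""
    rms = float(np.sqrt(np.mean(np.square(audio.samples))))
    if rms < _SILENCE_RMS:
        raise DegenerateSignalError("cannot normalize an (effectively) silent signal")
    gain = 10.0 ** (target_db / 20.0) / rms
    return AudioSegment(samples=audio.samples * gain, rate=audio.rate)
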