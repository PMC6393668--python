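import numpy as np
import pytest
from hypothesis import settings

from scenecue import AudioSegment, SourceSpec, StimulusConfig, synth_envlike, synth_speechlike

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg() -> StimulusConfig:
    """The default stimulus constants (44.1 kHz, 5 s, 750 ms, 220, 4410, -23 dB)."""
    return StimulusConfig()


@pytest.fixture(scope="session")
def speech_source(cfg) -> AudioSegment:
    """One speech-like source long enough to build a trial from."""
    return synth_speechlike(
        SourceSpec("speechlike", cfg.source_duration + 1.0, seed=101, rate=cfg.sample_rate)
    )


@pytest.fixture(scope="session")
def env_source(cfg) -> AudioSegment:
    """One environment-like source long enough to build a trial from."""
    return synth_envlike(
        SourceSpec("envlike", cfg.source_duration + 1.0, seed=202, rate=cfg.sample_rate)
    )


def am_tone(
    mod_hz: float | None,
    duration: float = 3.0,
    rate: int = 44100,
    carrier_hz: float = 1000.0,
    depth: float = 0.8,
    floor: float = 0.2,
) -> tuple[AudioSegment, np.ndarray]:
    """Amplitude-modulated tone with a known modulator (None -> constant 0.5).

    Returns the audio and the ground-truth modulator array.
    """
    n = round(duration * rate)
    t = np.arange(n) / rate
    carrier = np.sin(2 * np.pi * carrier_hz * t)
    if mod_hz is None:
        modulator = np.full(n, 0.5)
    else:
        modulator = floor + depth * 0.5 * (1 + np.sin(2 * np.pi * mod_hz * t))
    return AudioSegment(samples=carrier * modulator, rate=rate), modulator


def central_corr(a: np.ndarray, b: np.ndarray, fraction: float = 0.8) -> float:
    """Pearson correlation over the central ``fraction`` of two sequences."""
    n = len(a)
    lo = round(n * (1 - fraction) / 2)
    hi = n - lo
    return float(np.corrcoef(a[lo:hi], b[lo:hi])[0, 1])
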