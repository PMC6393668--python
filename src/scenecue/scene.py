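"""Per-trial diotic scene assembly.

Each trial presents two simultaneous sound streams from a single central
(virtual) source: both streams are prepared to the same duration and RMS
level, a one-back repetition target is embedded in exactly one of them,
and the two are summed linearly — the superposition model under which all
sounds in a scene mix into a single waveform at the ear.

In speech/environment mode the environment stream is first given
speech-like coarse dynamics by envelope transfer, so the two streams are
matched in low-frequency rhythmicity and only their higher-level content
distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import AudioSegment, StimulusConfig, cut_segment, normalize_rms, to_mono
from .envelope import extract_envelope, transfer_envelope
from .repetition import RepetitionAnnotation, embed_repetition

__all__ = ["TrialStimulus", "mix_scene", "build_trial_stimulus", "prepare_source"]

_PEAK_CEILING = 0.99


@dataclass(frozen=True)
class TrialStimulus:
    """One trial's rendered scene with its target bookkeeping."""

    mix: AudioSegment
    stream_a: AudioSegment
    stream_b: AudioSegment
    target_stream: str  # "A" | "B"
    annotation: RepetitionAnnotation
    config: StimulusConfig

    def __post_init__(self) -> None:
        if self.target_stream not in ("A", "B"):
            raise ValueError(f"target_stream must be 'A' or 'B', got {self.target_stream!r}")


def mix_scene(a: AudioSegment, b: AudioSegment) -> AudioSegment:
    """Sample-wise linear sum, with a single shape-preserving peak guard.

    If the sum exceeds full scale anywhere, the whole mix is rescaled by one
    scalar to a 0.99 peak, so relative structure is untouched.
    """
    if a.n_samples != b.n_samples:
        raise ValueError(f"length mismatch: {a.n_samples} vs {b.n_samples} samples")
    if a.rate != b.rate:
        raise ValueError(f"rate mismatch: {a.rate} vs {b.rate} Hz")
    out = a.samples + b.samples
    peak = float(np.max(np.abs(out)))
    if peak > 1.0:
        out = out * (_PEAK_CEILING / peak)
    return AudioSegment(samples=out, rate=a.rate)


def prepare_source(source: AudioSegment, cfg: StimulusConfig) -> AudioSegment:
    """Source preparation pipeline: mono, central cut, RMS normalization.

    The cut length is scene duration + repetition duration, leaving room for
    the repetition to be embedded and the stream trimmed back to scene
    length afterwards.
    """
    x = to_mono(source)
    x = cut_segment(x, cfg.source_duration, anchor="center")
    return normalize_rms(x, cfg.target_level_db)


def build_trial_stimulus(
    source_a: AudioSegment,
    source_b: AudioSegment,
    target_stream: str,
    mode: str,
    cfg: StimulusConfig,
    seed: int,
    cut_sample: int | None = None,
) -> TrialStimulus:
    """Assemble one trial: prepare both streams, envelope-transfer the
    environment stream (speech_env mode), embed the target, overlay.

    In ``speech_env`` mode stream A is the speech source and stream B the
    environment source; B receives A's extracted envelope as donor.  In
    ``speech_speech`` mode both streams pass through unchanged dynamics.
    Deterministic given ``seed`` (which decides the cut sample unless one is
    given explicitly).
    """
    if mode not in ("speech_env", "speech_speech"):
        raise ValueError(f"unknown mode {mode!r}")
    if target_stream not in ("A", "B"):
        raise ValueError(f"target_stream must be 'A' or 'B', got {target_stream!r}")

    a = prepare_source(source_a, cfg)
    b = prepare_source(source_b, cfg)
    if mode == "speech_env":
        donor = extract_envelope(a, cfg.envelope_min_separation)
        b = transfer_envelope(
            b, donor, cfg.envelope_min_separation, cfg.target_level_db
        )

    R = cfg.repetition_samples
    ramp = cfg.ramp_samples
    trim = R - ramp

    if target_stream == "A":
        tgt, other = a, b
    else:
        tgt, other = b, a
    tgt_embedded, annotation = embed_repetition(tgt, cfg, cut_sample=cut_sample, seed=seed)
    # Keep the untouched stream on the same timeline as the embedded one:
    # embedding drops `trim` leading samples, so cut the plain stream the same way.
    other_cut = cut_segment(other, cfg.segment_duration, anchor="offset", offset=trim)

    tgt_final = normalize_rms(tgt_embedded, cfg.target_level_db)
    other_final = normalize_rms(other_cut, cfg.target_level_db)

    if target_stream == "A":
        stream_a, stream_b = tgt_final, other_final
    else:
        stream_a, stream_b = other_final, tgt_final
    return TrialStimulus(
        mix=mix_scene(stream_a, stream_b),
        stream_a=stream_a,
        stream_b=stream_b,
        target_stream=target_stream,
        annotation=annotation,
        config=cfg,
    )


def diotic_export(stimulus: TrialStimulus) -> AudioSegment:
    """Two identical channels (diotic presentation) for player compatibility."""
    mono = stimulus.mix.samples
    return AudioSegment(samples=np.vstack([mono, mono]), rate=stimulus.mix.rate)
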