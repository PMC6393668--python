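"""Sample-accurate one-back repetition embedding with cross-fade splicing.

A repetition target is built by cutting the source waveform at a randomly
chosen sample, replaying the 750 ms that immediately preceded the cut, and
splicing beginning, repetition and remainder together with 220-sample
(5 ms) linear cross-fades so the transitions carry no click artifacts.
Splice arithmetic: with repetition length ``R`` and ramp ``r``, each
cross-fade absorbs ``r`` samples, so the spliced stream is ``R - 2r``
samples longer than the source and the two epochs start ``R - r`` samples
apart.  The stream is finally trimmed back to the configured 5.0-s scene
duration with the complete repetition pair kept away from the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_core import AudioSegment, StimulusConfig

__all__ = [
    "RepetitionAnnotation",
    "crossfade_concat",
    "embed_repetition",
    "draw_annotation",
    "locate_repetition",
    "LagScanResult",
]


@dataclass(frozen=True)
class RepetitionAnnotation:
    """Where the repetition pair lives, in output-sample coordinates.

    ``first_onset`` / ``second_onset`` index the original and the repeated
    epoch in the *returned* (trimmed) stimulus; ``cut_sample`` indexes the
    source waveform.  Outside the cross-fade ramps the two epochs are
    verbatim copies of each other: ``second_onset - first_onset ==
    rep_length - ramp_samples`` exactly.
    """

    cut_sample: int
    rep_length: int
    first_onset: int
    second_onset: int
    ramp_samples: int

    def __post_init__(self) -> None:
        if self.second_onset - self.first_onset != self.rep_length - self.ramp_samples:
            raise ValueError(
                "annotation violates splice arithmetic: second_onset - first_onset "
                f"= {self.second_onset - self.first_onset}, expected "
                f"{self.rep_length - self.ramp_samples}"
            )

    @property
    def lag(self) -> int:
        """Lag at which the two epochs repeat: ``rep_length - ramp_samples``."""
        return self.rep_length - self.ramp_samples

    def onset_seconds(self, rate: int) -> float:
        """Onset of the *repeated* epoch — the moment a repetition becomes
        detectable — in seconds from stream start."""
        return self.second_onset / rate


def crossfade_concat(a: AudioSegment, b: AudioSegment, ramp: int) -> AudioSegment:
    """Concatenate two segments with a linear cross-fade of ``ramp`` samples.

    In the overlap, the down-ramped tail of ``a`` and the up-ramped head of
    ``b`` are summed with weights that are linear and sum to one at every
    sample, so constant inputs are conserved exactly.  Output length is
    ``len(a) + len(b) - ramp``.
    """
    if a.rate != b.rate:
        raise ValueError(f"rate mismatch: {a.rate} vs {b.rate} Hz")
    if ramp < 1:
        raise ValueError(f"ramp must be >= 1 sample, got {ramp}")
    if ramp > a.n_samples or ramp > b.n_samples:
        raise ValueError(
            f"ramp of {ramp} samples exceeds an input "
            f"(lengths {a.n_samples}, {b.n_samples})"
        )
    xa, xb = a.samples, b.samples
    w_down = np.linspace(1.0, 0.0, ramp)
    w_up = 1.0 - w_down
    out = np.empty(len(xa) + len(xb) - ramp)
    out[: len(xa) - ramp] = xa[: len(xa) - ramp]
    out[len(xa) - ramp : len(xa)] = xa[len(xa) - ramp :] * w_down + xb[:ramp] * w_up
    out[len(xa) :] = xb[ramp:]
    return AudioSegment(samples=out, rate=a.rate)


def _admissible_cut_range(cfg: StimulusConfig) -> tuple[int, int]:
    """Inclusive range of source cut samples keeping the full repetition pair
    (with ramps) at least ``cfg.edge_margin`` from the trimmed stream edges."""
    R = cfg.repetition_samples
    ramp = cfg.ramp_samples
    margin = round(cfg.edge_margin * cfg.sample_rate)
    # After trimming, epochs sit at cut - 2R + ramp and cut - R (see embed).
    lo = margin + 2 * R - ramp
    hi = cfg.segment_samples - margin
    if lo > hi:
        raise ValueError("segment too short for the configured repetition and margins")
    return lo, hi


def draw_annotation(cfg: StimulusConfig, seed: int) -> RepetitionAnnotation:
    """Draw the cut sample (and hence epoch onsets) a stimulus built with the
    same seed will have, without synthesizing any audio.

    This is the single source of randomness shared between design generation
    and audio rendering: the first draw of ``default_rng(seed)`` decides the
    cut, so trial tables and rendered stimuli always agree on target onsets.
    """
    lo, hi = _admissible_cut_range(cfg)
    rng = np.random.default_rng(seed)
    cut = int(rng.integers(lo, hi + 1))
    return _annotation_from_cut(cut, cfg)


def _annotation_from_cut(cut: int, cfg: StimulusConfig) -> RepetitionAnnotation:
    R = cfg.repetition_samples
    ramp = cfg.ramp_samples
    trim = R - ramp  # leading samples dropped when trimming back to segment length
    return RepetitionAnnotation(
        cut_sample=cut,
        rep_length=R,
        first_onset=cut - trim - R,
        second_onset=cut - trim - ramp,
        ramp_samples=ramp,
    )


def embed_repetition(
    x: AudioSegment,
    cfg: StimulusConfig,
    cut_sample: int | None = None,
    seed: int | None = None,
) -> tuple[AudioSegment, RepetitionAnnotation]:
    """Embed a one-back repetition and trim to the scene duration.

    With ``A = x[:cut]``, ``B = x[cut-R:cut]`` (the 750 ms just heard) and
    ``C = x[cut:]``, the spliced stream is ``crossfade(crossfade(A, B), C)``;
    it is then trimmed by ``R - ramp`` leading samples and cut to exactly
    ``cfg.segment_duration``.  If ``cut_sample`` is None it is drawn
    uniformly from the admissible range using ``seed``.
    """
    R = cfg.repetition_samples
    ramp = cfg.ramp_samples
    needed = cfg.segment_samples + R
    if x.n_samples < needed:
        raise ValueError(
            f"source of {x.n_samples} samples is too short: embedding needs "
            f"segment + repetition = {needed} samples"
        )
    lo, hi = _admissible_cut_range(cfg)
    if cut_sample is None:
        if seed is None:
            raise ValueError("either cut_sample or seed must be given")
        annotation = draw_annotation(cfg, seed)
        cut = annotation.cut_sample
    else:
        cut = int(cut_sample)
        if not lo <= cut <= hi:
            raise ValueError(
                f"cut_sample {cut} outside admissible range [{lo}, {hi}]"
            )
        annotation = _annotation_from_cut(cut, cfg)

    a = AudioSegment(samples=x.samples[:cut], rate=x.rate)
    b = AudioSegment(samples=x.samples[cut - R : cut], rate=x.rate)
    c = AudioSegment(samples=x.samples[cut:], rate=x.rate)
    spliced = crossfade_concat(crossfade_concat(a, b, ramp), c, ramp)
    # Pre-trim length is len(x) + R - 2*ramp; drop R - ramp leading samples,
    # then keep exactly the scene duration.
    trim = R - ramp
    trimmed = spliced.samples[trim : trim + cfg.segment_samples]
    if len(trimmed) < cfg.segment_samples:
        raise ValueError("internal error: spliced stream shorter than scene duration")
    return AudioSegment(samples=trimmed, rate=x.rate), annotation


@dataclass(frozen=True)
class LagScanResult:
    """Outcome of a brute-force self-similarity scan at a fixed lag."""

    onset_estimate: int
    min_msd: float
    median_msd: float

    @property
    def score(self) -> float:
        """Contrast between best and typical window mismatch; near 1 when a
        true repetition exists, near 0 for unrelated audio."""
        if self.median_msd <= 0:
            return 0.0
        return 1.0 - self.min_msd / self.median_msd


def locate_repetition(
    x: AudioSegment,
    lag: int,
    window_seconds: float = 0.100,
    ramp: int = 220,
) -> LagScanResult:
    """Brute-force scan for a repeated epoch at a known lag.

    Slides a window over the mean squared difference between the stream and
    its lag-shifted copy; where a genuine repetition lies, the two epochs are
    verbatim copies and the mismatch drops to (numerically) zero.  Returns
    the estimated first-epoch onset: the start of the earliest minimal
    window, minus the cross-fade ramp that precedes the verbatim region.

    This is a diagnostic/validation utility, not a general-purpose
    repetition detector for arbitrary external audio.
    """
    s = x.samples
    if lag <= 0 or lag >= len(s):
        raise ValueError(f"lag {lag} outside (0, {len(s)})")
    w = round(window_seconds * x.rate)
    d2 = np.square(s[:-lag] - s[lag:])
    if len(d2) < w:
        raise ValueError("signal too short for the scan window")
    csum = np.concatenate(([0.0], np.cumsum(d2)))
    msd = (csum[w:] - csum[:-w]) / w  # mean sq. diff of window starting at i
    best = float(np.min(msd))
    med = float(np.median(msd))
    tol = best + 1e-12 + 1e-9 * med
    first_idx = int(np.argmax(msd <= tol))
    return LagScanResult(onset_estimate=first_idx - ramp, min_msd=best, median_msd=med)
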