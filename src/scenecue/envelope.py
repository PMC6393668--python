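"""Peak-spline envelope extraction and envelope transfer.

The envelope of a waveform is obtained by cubic-spline interpolation over
local maxima of the rectified signal, with consecutive peaks forced at
least ``min_sep`` samples apart (4410 samples = 0.1 s at 44.1 kHz by
default).  The coarse 0.1-s granularity deliberately preserves the fine
structure of the enveloped sound: only sub-10-Hz dynamics are captured.

Envelope *transfer* divides a signal by its own envelope (whitening its
coarse dynamics) and multiplies by a donor envelope, imposing the donor's
slow amplitude rhythm — the operation used to give stationary environment
textures the quasi-rhythmic dynamics of speech.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks as _scipy_find_peaks

from .audio_core import AudioSegment, DegenerateSignalError, normalize_rms

__all__ = [
    "Envelope",
    "find_peaks_minsep",
    "extract_envelope",
    "whitening_envelope",
    "transfer_envelope",
]

#: Positivity floor, as a fraction of the signal's peak amplitude.
EPS_FRACTION = 1e-4


@dataclass(frozen=True)
class Envelope:
    """A nonnegative amplitude envelope sampled at the audio rate."""

    values: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if np.any(values < 0):
            raise ValueError("envelope values must be nonnegative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def find_peaks_minsep(x: np.ndarray, min_sep: int) -> np.ndarray:
    """Local maxima of ``|x|`` with pairwise index gaps >= ``min_sep``.

    Conflicts between close candidates are resolved greedily by descending
    magnitude, ties broken toward the earlier index.  The global maximum of
    ``|x|`` is always among the candidates, so non-constant input yields at
    least one peak.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot find peaks of an empty signal")
    if min_sep < 1:
        raise ValueError(f"min_sep must be >= 1, got {min_sep}")
    mag = np.abs(x)

    candidates = set(_scipy_find_peaks(mag)[0].tolist())
    candidates.add(int(np.argmax(mag)))
    # Sort by descending magnitude, earlier index first among ties.
    order = sorted(candidates, key=lambda i: (-mag[i], i))

    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= min_sep for a in accepted):
            accepted.append(idx)
    return np.array(sorted(accepted), dtype=np.intp)


def extract_envelope(x: AudioSegment, min_sep: int = 4410) -> Envelope:
    """Cubic-spline envelope through the min-separated peaks of ``|x|``.

    Virtual peaks are prepended/appended at the first and last sample (with
    value ``|x|`` there) so the spline covers the full support, and the
    result is clamped below at ``EPS_FRACTION`` of the peak amplitude so it
    is safe to divide by.
    """
    samples = x.samples
    if samples.ndim != 1:
        raise ValueError("extract_envelope expects mono audio")
    peak_amp = float(np.max(np.abs(samples)))
    if peak_amp < 1e-12 or np.ptp(samples) < 1e-12:
        raise DegenerateSignalError("cannot extract the envelope of a constant signal")

    mag = np.abs(samples)
    last = len(samples) - 1
    # Virtual peaks at the first and last sample participate in the min-sep
    # constraint: a knot almost touching an endpoint would let the cubic
    # spline ring wildly, so interior peaks too close to an edge are dropped.
    idx = [i for i in find_peaks_minsep(samples, min_sep) if min_sep <= i <= last - min_sep]
    idx_arr = np.array(sorted({0, *idx, last}), dtype=np.intp)

    spline = CubicSpline(idx_arr, mag[idx_arr])
    values = spline(np.arange(len(samples)))
    eps = EPS_FRACTION * peak_amp
    return Envelope(values=np.maximum(values, eps), rate=x.rate)


def whitening_envelope(x: AudioSegment, min_sep: int = 4410) -> Envelope:
    """The envelope a signal is divided by during transfer.

    The raw peak-spline envelope carries interpolation wobble at the knot
    scale (peak picking on a noise carrier is an extreme-value estimate), so
    it is low-passed with a centered moving average of 1.5 x ``min_sep``
    samples before use as a divisor.  The peak-spline envelope is only
    defined up to ~1/(2 x 0.1 s) = 5 Hz anyway, so this costs little genuine
    dynamics while keeping the whitened signal's level stable.
    """
    raw = extract_envelope(x, min_sep)
    width = max(1, round(1.5 * min_sep))
    smoothed = uniform_filter1d(raw.values, width, mode="nearest")
    eps = EPS_FRACTION * float(np.max(np.abs(x.samples)))
    return Envelope(values=np.maximum(smoothed, eps), rate=x.rate)


def transfer_envelope(
    target: AudioSegment,
    donor_env: Envelope,
    min_sep: int = 4410,
    target_level_db: float = -23.0,
) -> AudioSegment:
    """Impose ``donor_env`` on ``target``, preserving its fine structure.

    The target is divided by its own (smoothed, eps-floored) peak-spline
    envelope — see :func:`whitening_envelope` — multiplied by the donor
    envelope, and re-normalized to ``target_level_db`` so enveloping never
    changes overall level.
    """
    if target.n_samples != len(donor_env):
        raise ValueError(
            f"length mismatch: target has {target.n_samples} samples, "
            f"donor envelope {len(donor_env)}"
        )
    if target.rate != donor_env.rate:
        raise ValueError(f"rate mismatch: {target.rate} vs {donor_env.rate} Hz")
    own = whitening_envelope(target, min_sep)
    whitened = target.samples / own.values  # own.values is clamped > 0
    out = AudioSegment(samples=whitened * donor_env.values, rate=target.rate)
    return normalize_rms(out, target_level_db)
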