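# Methods

## The experimental apparatus in brief

`scenecue` implements the computational side of a diotic, object-based
auditory attention experiment.  Two sound streams — a speech-like stream
and an environment-like stream (or two speech streams) — are overlaid
into one scene played from a single virtual source, so only the streams'
content, not their location, can guide attention.  On each trial a cue
points to one stream (validly on 70% of trials, invalidly on 20%, or not
at all on 10%), and the listener must detect a *one-back repetition*: a
750-ms epoch of one stream that is seamlessly replayed immediately after
itself.  The package synthesizes the stimuli, generates the cue-validity
designs, simulates a signal-detection-theory (SDT) observer in place of
human listeners, and runs the behavioral analysis (accuracy, reaction
time, d′, criterion, repeated-measures ANOVA, planned paired contrasts).

## Stimulus construction

**Source preparation.**  Sources are converted to mono by channel
averaging, cut to a fixed duration (the central window; ties broken
toward the earlier start), and normalized to −23 dB RMS re full scale.
The "−23 dB" is interpreted as dB relative to full-scale RMS (an RMS of
10^(−23/20) ≈ 0.0708 on the [−1, 1] scale); this is the simplest testable
convention and close in spirit to −23 LUFS broadcast practice, though no
loudness model is applied.  All processing is floating point; WAV output
is 32-bit float by default (PCM16 on request) so numerical invariants
survive a disk round trip.

**Repetition embedding.**  With repetition length R = 33 075 samples
(750 ms at 44.1 kHz) and ramp r = 220 samples (≈5 ms), the source is cut
at a sample `cut`; the beginning `x[:cut]`, the just-heard epoch
`x[cut−R:cut]`, and the remainder `x[cut:]` are concatenated with linear
cross-fades whose down/up weights sum to one at every overlap sample.
Each cross-fade absorbs r samples, so the spliced stream is R − 2r
samples longer than the source and the two epochs start R − r samples
apart; outside the ramps the epochs are verbatim copies, which is what
makes the target detectable in principle and lets a brute-force lag scan
verify every stimulus.  Sources are prepared at scene + repetition length
(5.75 s); after embedding, the stream is trimmed back to exactly 5.0 s
with the full repetition pair kept at least 250 ms from either edge.  The
admissible cut range is drawn uniformly per trial from a seeded generator;
the same first draw is used by the design generator and the audio
renderer, so trial tables and rendered audio always agree on target
onsets.

**Envelope extraction and transfer.**  The amplitude envelope is a cubic
spline through local maxima of |x| that are at least 4410 samples (0.1 s)
apart, conflicts resolved greedily by descending magnitude (earlier index
wins ties).  Virtual knots are placed at the first and last sample with
the local |x| value; interior peaks closer than the minimum separation to
an endpoint are dropped, because a knot nearly touching an endpoint makes
the cubic spline ring by an order of magnitude.  The envelope is clamped
below at ε = 10⁻⁴ of the peak amplitude so it is safe to divide by.

Envelope *transfer* divides the target by its own envelope and multiplies
by a donor envelope, then re-normalizes to the configured level.  The
whitening divisor is additionally low-passed by a centered moving average
of 1.5 × the peak separation (≈0.15 s): peak picking on a noise carrier
is an extreme-value estimate and the raw spline carries knot-scale wobble
that destabilizes the division, while the peak envelope is in any case
only defined below ≈5 Hz (0.1-s knot spacing), so the smoothing costs
little genuine dynamics.  In speech/environment mode the environment
stream receives the speech stream's envelope, equalizing the two streams'
low-frequency rhythmicity.

**Mixing.**  Component streams are normalized to the same −23 dB RMS
level (a 0-dB target-to-masker ratio; the mixing gain is not otherwise
specified by the design, and equal levels are the neutral choice) and
summed linearly.  If the sum exceeds full scale the whole mix is rescaled
by a single scalar to a 0.99 peak, preserving the linear-superposition
structure.

## Synthetic sources

The generator stands in for field recordings and emulates exactly the two
statistical properties the pipeline depends on:

* **speech-like** — pink-noise carrier amplitude-modulated by a rectified
  sum of four random-phase sinusoids with frequencies in 4–8 Hz plus a DC
  floor of 0.25.  Natural speech envelopes carry prominent quasi-rhythmic
  energy in this syllabic band; using an analytically known modulator
  makes envelope-recovery tests exact.
* **environment-like** — stationary pink noise; its 1-s windowed RMS has
  a lower coefficient of variation than the speech-like source's, which
  is the "rather stationary" property the envelope-transfer step exists
  to correct.

Both are deterministic given the seed and peak-guarded to [−1, 1].  They
do **not** emulate spectral tilt details, formants, intelligibility, or
the recognizability of real environmental scenes, so passing tests show
the *pipeline* behaves correctly, not that the synthetic audio would be
perceptually equivalent to the original stimuli.

## Trial designs

Cue-condition counts are exact per session via largest-remainder
apportionment (300 trials → 210 valid / 60 invalid / 30 neutral), not
binomial draws: the design percentages are part of the paradigm, and
exact counts make the generator testable.  Within each condition the
target stream is balanced 50/50 up to rounding.  Trial order is a seeded
global shuffle, then split into blocks (3 × 100 for the
speech/environment experiment; 5 × 60 for the two-speech experiment).
Fixation and cue-to-scene intervals are uniform jitters (1.0–2.0 s and
0.5–0.75 s; both 1.0–1.5 s in the two-speech preset, whose cue is an
auditory pre-play of the cued voice rather than a visual label).

## The simulated observer

One yes/no SDT decision per trial, with equal-variance Gaussian evidence.
The task itself is continuous listening, but the analysis applied to it is
standard yes/no SDT, so the generative model matches the analysis model —
this alignment is what makes observer parameter recovery a meaningful
end-to-end check of the apparatus.

Parameters are (d′, c) per attention state: *attended* (cued stream holds
the target), *unattended* (cue pointed elsewhere), *neutral* (no cue).
The criterion uses the standard relative-to-midpoint convention: the
absolute cutoff is λ = c + d′/2, hence hit probability Φ(d′/2 − c) and a
model-intrinsic pre-target response probability Φ(−d′/2 − c).  Under this
convention the analysis-side estimators d̂′ = z(H) − z(FA) and
ĉ = −(z(H) + z(FA))/2 recover the generative parameters exactly in
expectation.  Premature responses (the task's operational false alarms:
presses before the target has played) occur with that model-intrinsic
probability by default and land uniformly in the pre-target interval;
setting a numeric `premature_rate` instead scales the neutral-condition
rate, with more liberal conditions proportionally more premature-prone.

Reaction times for detections are lognormal (default median 0.75 s,
σ = 0.3 log-units) added to the target onset, truncated to the stream
end, and shifted by attention: attended −100 ms, neutral 0, unattended
+100 ms.  A symmetric shift (rather than a discount for attended targets
only) is required for the characteristic three-level RT ordering
valid < neutral < invalid; a one-sided shift would leave neutral and
invalid equal in expectation.

Default presets (d′ = 3.3 / 2.4 / 1.9 and c = 0.5 / 0.6 / 0.7 for
attended / neutral / unattended; slightly lower sensitivities in the
two-speech preset) produce accuracies of roughly 88 / 73 / 60% and ~100-ms
cue-validity RT effects — the qualitative structure of the published
condition tables.  They are simulation presets, not estimates of any real
listener.

## Behavioral analysis

**Scoring.**  A response in [target onset, stream end] is a hit; a
response before target onset is a false alarm; no response is a miss;
responses after stream end are ignored (such trials are misses — no
response deadline beyond the stream itself is assumed).  Hit rate is
computed over trials that reached the target (hits + misses): a trial
ended by a premature press never offered the target opportunity, and this
conditioning keeps d′ estimation unbiased.  The false-alarm denominator
is all trials of the cell — each trial contributes exactly one pre-target
noise opportunity.

**SDT indices.**  d′ = z(H) − z(FA), c = −(z(H) + z(FA))/2, with the
1/(2N) correction applied to extreme rates (0 → 1/(2N), 1 → 1 − 1/(2N))
before the z-transform.

**Inference.**  Planned contrasts are two-tailed paired-samples t-tests
(degenerate zero-variance differences raise an error rather than report
t = ±∞).  Repeated-measures ANOVAs use the standard balanced sums-of-
squares decomposition; each within-subject effect is tested against its
own effect-by-subject interaction, with uncorrected degrees of freedom
(no sphericity correction — the reference analyses report plain
F(2,18)-style dfs).  The implementation is validated against a
sequential-projection oracle on dummy-coded design matrices and against
statsmodels' `AnovaRM` F statistics.

Condition summaries report per-cell accuracy (%), mean hit RT (ms), d′
and c, with across-participant SEMs; cells are cue condition × target
stream for the two-stream factorial experiment and cue condition alone
for the two-speech experiment.  Empty cells are reported missing, never
fabricated.

## Problem sizes and numerical choices

* Default end-to-end runs simulate designs and responses on the
  annotation timeline only; audio rendering is opt-in (`--render-audio`),
  keeping a 10-participant run well under a second.
* Parameter-recovery checks use 10 000 trials per condition (a single
  30 000-trial design with equal condition proportions); recovery error
  is typically < 0.09 in d′ against a ±0.15 acceptance band.
* Cohort-level ordering checks use 20 cohorts of 10 participants × 300
  trials, the reference cohort size.
* The lag-scan validator slides a 100-ms mean-squared-difference window
  at lag R − r; within the embedded pair the mismatch is numerically
  zero, and the first window reaching the minimum (within 1e−9 relative)
  marks the epoch.  On stimuli with a genuine repetition its contrast
  score is ≈1; on unrelated audio it stays well below 0.95.
* Envelope correlations are evaluated over the central 80% of the
  signal; spline edge effects extend about two knot spacings (≈0.2 s)
  from each end.
* Exact condition counts, seeded generators everywhere, and
  largest-remainder apportionment make every artifact reproducible
  bit-for-bit from one master seed (per-participant seeds are consecutive
  draws of `default_rng(master_seed)`, all below 2³¹).

## Known limitations

* Synthetic sources are statistical stand-ins; no claim is made about
  perceptual equivalence to real speech or environmental recordings.
* The observer has no learning, fatigue, or drift-diffusion dynamics;
  RT distributions are lognormal by construction.
* The human condition means of the original study are not reproducible
  computationally; the simulator reproduces their qualitative structure
  (orderings and effect directions), not their numeric cell values.
* Diotic presentation is represented as a single channel (with an
  optional duplicated-channel export); no HRTF or playback calibration.
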