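"""Cue-validity trial designs with jittered event timing.

The task is a Posner-style attentional cueing paradigm: on each trial a cue
directs attention to one of two simultaneous sound streams (or to neither,
in the neutral condition) before the scene plays.  Cue validity is 70%,
with 20% invalid and 10% neutral cues; the repetition target falls in
either stream on half the trials.  Condition counts are exact per session
(largest-remainder apportionment), not binomial draws, so a generated
session reproduces the design percentages exactly; trial order is a seeded
shuffle.

Experiment presets:

* ``exp1``: 3 blocks x 100 trials, visual cue, fixation jitter 1.0-2.0 s,
  cue-to-audio jitter 0.5-0.75 s, speech vs. enveloped-environment streams.
* ``exp2``: 5 blocks x 60 trials, auditory pre-play cue (the first 1.0 s of
  the cued voice), both jitters 1.0-1.5 s, two speech streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio_core import StimulusConfig
from .repetition import draw_annotation

__all__ = [
    "DesignConfig",
    "generate_design",
    "validate_trial_table",
    "largest_remainder_counts",
    "exp1_design",
    "exp2_design",
    "write_design_csv",
    "read_design_csv",
]

TRIAL_TABLE_COLUMNS = [
    "trial_id",
    "block",
    "cue_condition",
    "cued_stream",
    "target_stream",
    "target_onset_s",
    "fixation_interval_s",
    "cue_interval_s",
    "stimulus_seed",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of one experimental session's trial design."""

    n_blocks: int = 3
    trials_per_block: int = 100
    p_valid: float = 0.7
    p_invalid: float = 0.2
    p_neutral: float = 0.1
    target_stream_balance: float = 0.5
    fixation_jitter: tuple[float, float] = (1.0, 2.0)
    cue_to_audio_jitter: tuple[float, float] = (0.5, 0.75)
    cue_kind: str = "visual_label"  # visual_label | auditory_preplay | none
    mode: str = "speech_env"  # stream classes: speech_env | speech_speech
    seed: int = 0
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)

    def __post_init__(self) -> None:
        total = self.p_valid + self.p_invalid + self.p_neutral
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cue-condition proportions must sum to 1, got {total}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        for lo, hi in (self.fixation_jitter, self.cue_to_audio_jitter):
            if lo > hi:
                raise ValueError("jitter ranges must satisfy low <= high")
        if self.cue_kind not in ("visual_label", "auditory_preplay", "none"):
            raise ValueError(f"unknown cue_kind {self.cue_kind!r}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixation_jitter"] = list(self.fixation_jitter)
        d["cue_to_audio_jitter"] = list(self.cue_to_audio_jitter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "stimulus" in d and isinstance(d["stimulus"], dict):
            d["stimulus"] = StimulusConfig(**d["stimulus"])
        for key in ("fixation_jitter", "cue_to_audio_jitter"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "DesignConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def exp1_design(seed: int = 0) -> DesignConfig:
    """Speech + enveloped-environment session: 3 x 100 trials, visual cue."""
    return DesignConfig(seed=seed)


def exp2_design(seed: int = 0) -> DesignConfig:
    """Two-speech-streams session: 5 x 60 trials, auditory pre-play cue."""
    return DesignConfig(
        n_blocks=5,
        trials_per_block=60,
        fixation_jitter=(1.0, 1.5),
        cue_to_audio_jitter=(1.0, 1.5),
        cue_kind="auditory_preplay",
        mode="speech_speech",
        seed=seed,
    )


def largest_remainder_counts(n: int, proportions: list[float]) -> list[int]:
    """Apportion ``n`` into integer counts matching ``proportions`` exactly.

    Floors of ``n * p`` first, then the remaining units go to the cells with
    the largest fractional remainders (earlier cell wins ties).
    """
    exact = [n * p for p in proportions]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - np.floor(exact[i])), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_design(cfg: DesignConfig) -> pd.DataFrame:
    """Generate one session's trial table, deterministic given ``cfg.seed``.

    Cue-condition counts are exact (largest remainder); within each
    condition the target stream is balanced 50/50 up to rounding; valid
    cues point at the target stream, invalid at the other, neutral at
    neither.  Target onsets come from the same per-trial seeded draw the
    audio renderer uses, so the table and any rendered stimuli agree.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    n_valid, n_invalid, n_neutral = largest_remainder_counts(
        n, [cfg.p_valid, cfg.p_invalid, cfg.p_neutral]
    )

    rows: list[tuple[str, str, str]] = []
    for condition, count in (
        ("valid", n_valid),
        ("invalid", n_invalid),
        ("neutral", n_neutral),
    ):
        n_a, n_b = largest_remainder_counts(
            count, [cfg.target_stream_balance, 1.0 - cfg.target_stream_balance]
        )
        for target in ["A"] * n_a + ["B"] * n_b:
            if condition == "valid":
                cued = target
            elif condition == "invalid":
                cued = "B" if target == "A" else "A"
            else:
                cued = "none"
            rows.append((condition, cued, target))

    order = rng.permutation(len(rows))
    stimulus_seeds = rng.integers(0, _MAX_SEED, size=n)
    fixation = rng.uniform(*cfg.fixation_jitter, size=n)
    cue_iv = rng.uniform(*cfg.cue_to_audio_jitter, size=n)

    records = []
    for trial_id, idx in enumerate(order):
        condition, cued, target = rows[idx]
        seed_t = int(stimulus_seeds[trial_id])
        annot = draw_annotation(cfg.stimulus, seed_t)
        records.append(
            {
                "trial_id": trial_id,
                "block": trial_id // cfg.trials_per_block,
                "cue_condition": condition,
                "cued_stream": cued,
                "target_stream": target,
                "target_onset_s": annot.onset_seconds(cfg.stimulus.sample_rate),
                "fixation_interval_s": float(fixation[trial_id]),
                "cue_interval_s": float(cue_iv[trial_id]),
                "stimulus_seed": seed_t,
            }
        )
    return pd.DataFrame.from_records(records, columns=TRIAL_TABLE_COLUMNS)


def validate_trial_table(table: pd.DataFrame, cfg: DesignConfig | None = None) -> None:
    """Raise ``ValueError`` listing every violated trial-table invariant."""
    problems: list[str] = []
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")

    valid = table[table.cue_condition == "valid"]
    invalid = table[table.cue_condition == "invalid"]
    neutral = table[table.cue_condition == "neutral"]
    if not (valid.cued_stream == valid.target_stream).all():
        problems.append("valid trials must have cued_stream == target_stream")
    bad_inv = invalid[
        (invalid.cued_stream == invalid.target_stream) | (invalid.cued_stream == "none")
    ]
    if len(bad_inv):
        problems.append(
            f"invalid trials with wrong cueing at trial_id {bad_inv.trial_id.tolist()}"
        )
    if not (neutral.cued_stream == "none").all():
        problems.append("neutral trials must have cued_stream == 'none'")
    if table.trial_id.duplicated().any():
        problems.append("duplicate trial_ids")

    if cfg is not None:
        expected = largest_remainder_counts(
            cfg.n_trials, [cfg.p_valid, cfg.p_invalid, cfg.p_neutral]
        )
        actual = [len(valid), len(invalid), len(neutral)]
        if actual != expected:
            problems.append(f"condition counts {actual} != configured {expected}")
        for cond, sub in table.groupby("cue_condition"):
            n_a = (sub.target_stream == "A").sum()
            if abs(n_a - len(sub) * cfg.target_stream_balance) > 1:
                problems.append(f"target stream unbalanced in condition {cond}")
    if problems:
        raise ValueError("invalid trial table: " + "; ".join(problems))


def write_design_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=TRIAL_TABLE_COLUMNS)


def read_design_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
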