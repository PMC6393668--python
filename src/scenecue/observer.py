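"""Simulated signal-detection observer for the repetition-detection task.

The observer is the generative mirror of the analysis model: yes/no
detection under equal-variance Gaussian SDT, one decision per trial.  Its
sensitivity d' and criterion c depend on whether attention was cued to the
stream that carries the target (valid cue), away from it (invalid cue), or
nowhere (neutral), implementing the attentional facilitation/suppression
the cueing paradigm measures.

Conventions.  d' and c use the standard relative-to-midpoint
parameterization: the absolute evidence cutoff is ``lambda = c + d'/2``,
so the hit probability is ``Phi(d'/2 - c)`` and the model's own
pre-target (false-alarm) response probability is ``Phi(-d'/2 - c)``.
Because the generator and the analysis share one model, the analysis
pipeline's d'-hat and c-hat estimate exactly the generative parameters —
which is what makes observer parameter recovery a meaningful end-to-end
check of the whole apparatus.

Premature responses (the task's operational false alarms: button presses
before the target has played) are emitted independently of the target
evidence, uniformly over the pre-target interval.  Their probability is
``Phi(-lambda)`` of the trial's condition by default (the SDT model's own
noise-response rate); a numeric ``premature_rate`` instead scales the
neutral-condition rate, with more liberal conditions proportionally more
premature-prone.

Response times for hits are lognormal over the post-onset interval, with
an attention shift: attended targets are answered ``rt_attention_shift``
seconds faster and unattended ones that much slower than neutral,
reproducing the characteristic valid < neutral < invalid RT ordering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "ObserverParams",
    "simulate_observer",
    "exp1_observer",
    "exp2_observer",
    "write_responses_csv",
    "read_responses_csv",
]

RESPONSE_TABLE_COLUMNS = ["trial_id", "responded", "response_time_s", "premature"]

_MIN_RT = 0.050  # motor floor for simulated responses, s


@dataclass(frozen=True)
class ObserverParams:
    """Generative SDT parameters of one simulated participant."""

    dprime_attended: float = 3.3
    dprime_neutral: float = 2.4
    dprime_unattended: float = 1.9
    criterion_attended: float = 0.5
    criterion_neutral: float = 0.6
    criterion_unattended: float = 0.7
    rt_mu: float = float(np.log(0.75))  # log-seconds
    rt_sigma: float = 0.30  # log-seconds
    rt_attention_shift: float = 0.100  # seconds
    premature_rate: float | None = None  # None -> model's own Phi(-lambda)
    stream_duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dprime_attended", "dprime_neutral", "dprime_unattended"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.premature_rate is not None and not 0.0 <= self.premature_rate < 1.0:
            raise ValueError("premature_rate must be in [0, 1)")

    def condition_of(self, cue_condition: str) -> str:
        return {"valid": "attended", "invalid": "unattended", "neutral": "neutral"}[
            cue_condition
        ]

    def dprime(self, attention: str) -> float:
        return getattr(self, f"dprime_{attention}")

    def criterion(self, attention: str) -> float:
        return getattr(self, f"criterion_{attention}")

    def cutoff(self, attention: str) -> float:
        """Absolute evidence cutoff lambda = c + d'/2."""
        return self.criterion(attention) + self.dprime(attention) / 2.0

    def premature_prob(self, attention: str) -> float:
        """Per-trial probability of a pre-target (false-alarm) response."""
        if self.premature_rate is None:
            return float(norm.cdf(-self.cutoff(attention)))
        # Scale the neutral-condition rate by relative liberality.
        g = norm.cdf(-self.cutoff(attention)) / norm.cdf(-self.cutoff("neutral"))
        return float(np.clip(self.premature_rate * g, 0.0, 0.95))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def load(cls, path: str | Path) -> "ObserverParams":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def exp1_observer(seed: int = 0) -> ObserverParams:
    """Preset tuned to behave like a participant in the speech/environment
    session: high sensitivity when validly cued, clear costs when miscued.
    These are presets for simulation, not estimates of any real listener."""
    return ObserverParams(seed=seed)


def exp2_observer(seed: int = 0) -> ObserverParams:
    """Preset for the two-speech-streams session: the overall task is harder
    (two streams of the same class), so sensitivities sit lower."""
    return ObserverParams(
        dprime_attended=2.8,
        dprime_neutral=2.0,
        dprime_unattended=1.5,
        criterion_attended=0.5,
        criterion_neutral=0.6,
        criterion_unattended=0.7,
        rt_mu=float(np.log(0.85)),
        seed=seed,
    )


def _validate_design(design: pd.DataFrame) -> None:
    required = {"trial_id", "cue_condition", "target_stream", "target_onset_s"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = design[~design.cue_condition.isin(["valid", "invalid", "neutral"])]
    if len(bad):
        raise ValueError(
            f"design rows with unknown cue_condition at trial_id {bad.trial_id.tolist()}"
        )


def simulate_observer(design: pd.DataFrame, params: ObserverParams) -> pd.DataFrame:
    """Simulate one participant's responses to every trial of a design.

    Per trial: (1) with the condition's premature probability, respond at a
    uniform time before target onset (a false alarm); (2) otherwise draw
    evidence ``e ~ N(d'_eff, 1)`` and respond iff ``e`` clears the
    condition's cutoff; (3) responses land at target onset plus a lognormal
    latency, shifted by attention and truncated to the stream.  Deterministic
    given ``params.seed``.
    """
    _validate_design(design)
    rng = np.random.default_rng(params.seed)
    design = design.sort_values("trial_id").reset_index(drop=True)
    n = len(design)

    attention = np.array(
        [params.condition_of(c) for c in design.cue_condition], dtype=object
    )
    dprimes = np.array([params.dprime(a) for a in attention])
    cutoffs = np.array([params.cutoff(a) for a in attention])
    p_premature = np.array([params.premature_prob(a) for a in attention])
    shifts = np.where(
        attention == "attended",
        -params.rt_attention_shift,
        np.where(attention == "unattended", params.rt_attention_shift, 0.0),
    )
    onsets = design.target_onset_s.to_numpy(dtype=float)

    u_premature = rng.uniform(size=n)
    premature_times = rng.uniform(0.0, onsets)
    evidence = rng.normal(loc=dprimes, scale=1.0)
    latencies = rng.lognormal(mean=params.rt_mu, sigma=params.rt_sigma, size=n)

    is_premature = u_premature < p_premature
    detects = ~is_premature & (evidence > cutoffs)

    rts = np.full(n, np.nan)
    rts[is_premature] = premature_times[is_premature]
    hit_times = onsets + np.maximum(latencies + shifts, _MIN_RT)
    rts[detects] = np.minimum(hit_times[detects], params.stream_duration)

    responded = is_premature | detects
    return pd.DataFrame(
        {
            "trial_id": design.trial_id.to_numpy(),
            "responded": responded,
            "response_time_s": rts,
            "premature": is_premature,
        },
        columns=RESPONSE_TABLE_COLUMNS,
    )


def write_responses_csv(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False, columns=RESPONSE_TABLE_COLUMNS)


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["responded"] = df["responded"].astype(bool)
    df["premature"] = df["premature"].astype(bool)
    return df
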