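"""Behavioral analysis: trial scoring, SDT indices, contrasts, RM-ANOVA.

Scoring conventions
-------------------
A trial is a *hit* when the response falls in the window from target onset
to stream end, a *false alarm* when the response precedes target onset
(every trial offers exactly one pre-target noise opportunity), and a
*miss* when no response occurs.  Responses after stream end are ignored.
Accuracy is the hit rate over trials that reached the target (hits +
misses); the false-alarm rate uses all trials of the cell as denominator.

Sensitivity d' = z(H) - z(FA) and criterion c = -(z(H) + z(FA))/2 under
the equal-variance Gaussian model, with extreme proportions corrected by
the 1/(2N) rule (0 -> 1/(2N), 1 -> 1 - 1/(2N)) before the z-transform.

Inferential statistics are planned paired-samples t-tests (two-tailed)
and one-/two-way repeated-measures ANOVA with uncorrected degrees of
freedom; each within-subject effect is tested against its own
effect-by-subject interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDTScores",
    "TTestResult",
    "AnovaResult",
    "score_trials",
    "inverse_normal",
    "sdt_indices",
    "paired_ttest",
    "rm_anova",
    "summarize_participant",
    "summarize_experiment",
    "condition_table",
]


@dataclass(frozen=True)
class SDTScores:
    """Corrected rates and the derived SDT indices for one cell."""

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_signal: int
    n_noise_opportunities: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Repeated-measures ANOVA table: per-effect SS, df, MS, F, p."""

    design: str  # "oneway_rm" | "twoway_rm"
    effects: dict[str, dict[str, float]]
    ss_total: float

    def __getitem__(self, effect: str) -> dict[str, float]:
        return self.effects[effect]


def score_trials(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    stream_duration: float = 5.0,
) -> pd.DataFrame:
    """Join design and responses and label each trial hit/miss/false_alarm.

    RT (for hits) is measured from target onset.  Orphan trial_ids on
    either side raise a join error naming them.
    """
    d_ids = set(design.trial_id)
    r_ids = set(responses.trial_id)
    orphans = d_ids.symmetric_difference(r_ids)
    if orphans:
        raise ValueError(f"design/response tables disagree on trial_ids: {sorted(orphans)[:20]}")

    merged = design.merge(responses, on="trial_id", validate="one_to_one")
    onset = merged.target_onset_s.to_numpy(dtype=float)
    rt = merged.response_time_s.to_numpy(dtype=float)
    responded = merged.responded.to_numpy(dtype=bool) & ~np.isnan(rt)

    is_fa = responded & (rt < onset)
    is_hit = responded & (rt >= onset) & (rt <= stream_duration)
    # Responses after stream end are ignored; such trials count as misses.
    outcome = np.where(is_fa, "false_alarm", np.where(is_hit, "hit", "miss"))
    merged["outcome"] = outcome
    merged["rt_from_onset_s"] = np.where(is_hit, rt - onset, np.nan)
    return merged


def inverse_normal(p: float) -> float:
    """Standard normal quantile z with Phi(z) = p, for p strictly in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return float(stats.norm.ppf(p))


def sdt_indices(hits: int, n_signal: int, fas: int, n_noise: int) -> SDTScores:
    """d' and criterion from hit/false-alarm counts with the 1/(2N) correction."""
    if n_signal < 1 or n_noise < 1:
        raise ValueError("n_signal and n_noise must be >= 1")
    if not 0 <= hits <= n_signal:
        raise ValueError(f"hits {hits} outside [0, {n_signal}]")
    if not 0 <= fas <= n_noise:
        raise ValueError(f"false alarms {fas} outside [0, {n_noise}]")

    def corrected(count: int, n: int) -> float:
        rate = count / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    h = corrected(hits, n_signal)
    f = corrected(fas, n_noise)
    zh, zf = inverse_normal(h), inverse_normal(f)
    return SDTScores(
        hit_rate=h,
        fa_rate=f,
        dprime=zh - zf,
        criterion=-(zh + zf) / 2.0,
        n_signal=n_signal,
        n_noise_opportunities=n_noise,
    )


def paired_ttest(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-tailed paired-samples t-test on matched arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_ttest needs two 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired_ttest needs at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd < 1e-15:
        raise ValueError("differences have (numerically) zero variance; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def _check_balanced(data: pd.DataFrame, factors: list[str]) -> None:
    cells = data.groupby(["participant"] + factors, observed=True).size()
    if (cells != 1).any():
        bad = cells[cells != 1].index.tolist()
        raise ValueError(f"layout not one observation per participant x cell: {bad[:10]}")
    participants = data.participant.unique()
    level_sets = [sorted(data[f].unique()) for f in factors]
    expected = len(participants) * int(np.prod([len(ls) for ls in level_sets]))
    if len(data) != expected:
        raise ValueError("incomplete layout: some participants miss cells")


def rm_anova(data: pd.DataFrame, design: str) -> AnovaResult:
    """Repeated-measures ANOVA on cell means.

    ``data`` is long format with columns ``participant``, ``value``, and one
    factor column ``A`` (``design='oneway_rm'``) or two factor columns
    ``A``, ``B`` (``design='twoway_rm'``); every participant contributes
    exactly one value per cell.  Each effect is tested against its own
    subject interaction; no sphericity correction is applied.
    """
    if design not in ("oneway_rm", "twoway_rm"):
        raise ValueError(f"unknown design {design!r}")
    factors = ["A"] if design == "oneway_rm" else ["A", "B"]
    required = {"participant", "value", *factors}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    _check_balanced(data, factors)

    y = data.value.to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    n_subj = data.participant.nunique()
    if n_subj < 2:
        raise ValueError("rm_anova needs at least two participants")

    def ss_of(groupcols: list[str]) -> float:
        """n_per_group * sum of squared deviations of group means."""
        means = data.groupby(groupcols, observed=True).value.mean()
        n_per = len(data) / len(means)
        return float(n_per * np.sum((means.to_numpy() - grand) ** 2))

    def f_ratio(ms_eff: float, ms_err: float) -> float:
        # degenerate layouts (all cells equal) give 0/0; report F = 0
        if ms_err <= 1e-300:
            return 0.0 if ms_eff <= 1e-300 else float("inf")
        return ms_eff / ms_err

    effects: dict[str, dict[str, float]] = {}
    if design == "oneway_rm":
        a_levels = data.A.nunique()
        ss_a = ss_of(["A"])
        ss_subj = ss_of(["participant"])
        ss_err = ss_total - ss_a - ss_subj
        df_a = a_levels - 1
        df_err = (a_levels - 1) * (n_subj - 1)
        ms_a, ms_err = ss_a / df_a, ss_err / df_err
        f = f_ratio(ms_a, ms_err)
        effects["A"] = {
            "SS": ss_a,
            "df": df_a,
            "MS": ms_a,
            "F": f,
            "p": float(stats.f.sf(f, df_a, df_err)),
            "df_error": df_err,
            "SS_error": ss_err,
            "MS_error": ms_err,
        }
        effects["subject"] = {"SS": ss_subj, "df": n_subj - 1}
    else:
        a_levels = data.A.nunique()
        b_levels = data.B.nunique()
        ss_a = ss_of(["A"])
        ss_b = ss_of(["B"])
        ss_ab = ss_of(["A", "B"]) - ss_a - ss_b
        ss_subj = ss_of(["participant"])
        ss_as = ss_of(["participant", "A"]) - ss_a - ss_subj
        ss_bs = ss_of(["participant", "B"]) - ss_b - ss_subj
        ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_subj - ss_as - ss_bs

        layout = {
            "A": (ss_a, a_levels - 1, ss_as, (a_levels - 1) * (n_subj - 1)),
            "B": (ss_b, b_levels - 1, ss_bs, (b_levels - 1) * (n_subj - 1)),
            "A:B": (
                ss_ab,
                (a_levels - 1) * (b_levels - 1),
                ss_abs,
                (a_levels - 1) * (b_levels - 1) * (n_subj - 1),
            ),
        }
        for name, (ss_eff, df_eff, ss_err, df_err) in layout.items():
            ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
            f = f_ratio(ms_eff, ms_err)
            effects[name] = {
                "SS": ss_eff,
                "df": df_eff,
                "MS": ms_eff,
                "F": f,
                "p": float(stats.f.sf(f, df_eff, df_err)),
                "df_error": df_err,
                "SS_error": ss_err,
                "MS_error": ms_err,
            }
        effects["subject"] = {"SS": ss_subj, "df": n_subj - 1}
    return AnovaResult(design=design, effects=effects, ss_total=ss_total)


_CELL_MEASURES = ["accuracy_pct", "rt_ms", "dprime", "criterion"]


def summarize_participant(
    scored: pd.DataFrame, grouping: str = "by_condition_and_stream"
) -> pd.DataFrame:
    """Per-cell behavioral measures for one participant's scored trials.

    Cells are cue_condition x target_stream (``by_condition_and_stream``) or
    cue_condition alone (``by_condition``).  Accuracy is percent hits among
    trials that reached the target; RT is the mean hit latency in ms; d' and
    c follow the module's SDT conventions.  Empty cells are reported as NaN,
    never fabricated.
    """
    if grouping == "by_condition_and_stream":
        keys = ["cue_condition", "target_stream"]
    elif grouping == "by_condition":
        keys = ["cue_condition"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    records = []
    for cell, sub in scored.groupby(keys, observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        hits = int((sub.outcome == "hit").sum())
        misses = int((sub.outcome == "miss").sum())
        fas = int((sub.outcome == "false_alarm").sum())
        n_signal = hits + misses
        n_noise = len(sub)
        rec = dict(zip(keys, cell))
        rec["n_trials"] = n_noise
        if n_signal > 0:
            rec["accuracy_pct"] = 100.0 * hits / n_signal
            sdt = sdt_indices(hits, n_signal, fas, n_noise)
            rec["dprime"] = sdt.dprime
            rec["criterion"] = sdt.criterion
        else:
            rec["accuracy_pct"] = np.nan
            rec["dprime"] = np.nan
            rec["criterion"] = np.nan
        rts = sub.rt_from_onset_s.dropna()
        rec["rt_ms"] = 1000.0 * rts.mean() if len(rts) else np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_experiment(
    per_participant: dict[int | str, pd.DataFrame],
    grouping: str = "by_condition_and_stream",
) -> pd.DataFrame:
    """Condition summary across participants: mean and SEM per cell x measure.

    ``per_participant`` maps participant id to that participant's *scored*
    trial table (output of :func:`score_trials`).  SEM is the across-
    participants standard error, sd/sqrt(n).
    """
    frames = []
    for pid, scored in per_participant.items():
        summary = summarize_participant(scored, grouping)
        summary.insert(0, "participant", pid)
        frames.append(summary)
    long = pd.concat(frames, ignore_index=True)

    keys = ["cue_condition"] + (
        ["target_stream"] if grouping == "by_condition_and_stream" else []
    )
    rows = []
    for cell, sub in long.groupby(keys, observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        rec = dict(zip(keys, cell))
        rec["n_participants"] = len(sub)
        for measure in _CELL_MEASURES:
            vals = sub[measure].dropna().to_numpy()
            rec[measure] = vals.mean() if len(vals) else np.nan
            rec[f"{measure}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(rec)
    order = {"valid": 0, "neutral": 1, "invalid": 2}
    out = pd.DataFrame.from_records(rows)
    return out.sort_values(
        keys, key=lambda col: col.map(order) if col.name == "cue_condition" else col
    ).reset_index(drop=True)


def condition_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Reshape a condition summary into the publication-style layout:
    rows = measure (x stream when present), columns = Valid/Neutral/Invalid,
    cells "mean (SEM)"."""
    has_stream = "target_stream" in summary.columns
    rows = []
    streams = sorted(summary.target_stream.unique()) if has_stream else [None]
    for measure in _CELL_MEASURES:
        for stream in streams:
            sub = summary if stream is None else summary[summary.target_stream == stream]
            row: dict[str, str] = {"measure": measure}
            if stream is not None:
                row["stream"] = stream
            for cond in ["valid", "neutral", "invalid"]:
                cell = sub[sub.cue_condition == cond]
                if len(cell):
                    m = cell[measure].iloc[0]
                    s = cell[f"{measure}_sem"].iloc[0]
                    row[cond] = f"{m:.2f} ({s:.2f})" if np.isfinite(s) else f"{m:.2f}"
                else:
                    row[cond] = "-"
            rows.append(row)
    return pd.DataFrame.from_records(rows)
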