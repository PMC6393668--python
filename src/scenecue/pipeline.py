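"""One-command reproduction of a full synthetic experiment.

``run_experiment`` chains every stage: per-participant trial designs, an
optional audio render of the stimuli, simulated observer responses, trial
scoring, condition summaries, and the inferential statistics (RM-ANOVA
plus the planned paired contrasts on accuracy, RT, d' and criterion).
Everything derives deterministically from one master seed; the output
directory receives CSV/JSON artifacts and a manifest with content hashes
so two runs with the same config can be compared file by file.

Audio rendering is off by default — the design, observer and analysis
stages only need the annotation timeline — and switched on per run when
the WAV stimuli themselves are wanted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    paired_ttest,
    rm_anova,
    score_trials,
    summarize_experiment,
    summarize_participant,
)
from .audio_core import StimulusConfig, write_wav
from .design import DesignConfig, exp1_design, exp2_design, generate_design, write_design_csv
from .observer import ObserverParams, exp1_observer, exp2_observer, simulate_observer, write_responses_csv
from .scene import build_trial_stimulus
from .synth import SourceSpec, synth_envlike, synth_speechlike

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "participant_seeds"]

_MAX_SEED = 2**31 - 1

_MEASURES = ["accuracy_pct", "rt_ms", "dprime", "criterion"]
_CONTRAST_PAIRS = [("valid", "invalid"), ("valid", "neutral"), ("invalid", "neutral")]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated experiment run."""

    experiment: str = "exp1"  # exp1 | exp2
    n_participants: int = 10
    master_seed: int = 0
    render_audio: bool = False
    n_rendered_trials: int = 3  # per participant, when rendering
    output_dir: Path | None = None
    design: DesignConfig | None = None
    observer: ObserverParams | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"experiment must be 'exp1' or 'exp2', got {self.experiment!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class ExperimentResult:
    """In-memory bundle of everything a run produced."""

    config: RunConfig
    designs: dict[int, pd.DataFrame]
    responses: dict[int, pd.DataFrame]
    scored: dict[int, pd.DataFrame]
    summary: pd.DataFrame
    per_participant_cells: pd.DataFrame
    stats: dict
    manifest: dict | None = None


def participant_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-participant seeds: consecutive draws of
    ``default_rng(master_seed)``, each below 2**31."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, _MAX_SEED, size=n)]


def _base_design(cfg: RunConfig, seed: int) -> DesignConfig:
    if cfg.design is not None:
        base = cfg.design
        return DesignConfig(**{**base.to_dict(), "seed": seed, "stimulus": base.stimulus})
    return exp1_design(seed) if cfg.experiment == "exp1" else exp2_design(seed)


def _base_observer(cfg: RunConfig, seed: int) -> ObserverParams:
    if cfg.observer is not None:
        d = cfg.observer.to_dict()
        d["seed"] = seed
        return ObserverParams(**d)
    maker = exp1_observer if cfg.experiment == "exp1" else exp2_observer
    return maker(seed)


def _grouping(experiment: str) -> str:
    return "by_condition_and_stream" if experiment == "exp1" else "by_condition"


def _cell_means(scored_by_pid: dict[int, pd.DataFrame], grouping: str) -> pd.DataFrame:
    frames = []
    for pid, scored in scored_by_pid.items():
        s = summarize_participant(scored, grouping)
        s.insert(0, "participant", pid)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


def _condition_means(cells: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Participant x cue_condition means, collapsed over stream if present."""
    return (
        cells.groupby(["participant", "cue_condition"], observed=True)[measure]
        .mean()
        .unstack("cue_condition")
    )


def _run_contrasts(cells: pd.DataFrame, by_stream: bool) -> dict:
    """Planned paired t-tests per measure: collapsed over stream, and per
    stream when the design crosses target stream."""
    out: dict = {}
    for measure in _MEASURES:
        block: dict = {}
        wide = _condition_means(cells, measure)
        for a, b in _CONTRAST_PAIRS:
            pair = wide[[a, b]].dropna()
            try:
                res = paired_ttest(pair[a].to_numpy(), pair[b].to_numpy())
                block[f"{a}_vs_{b}"] = {"t": res.t, "df": res.df, "p": res.p}
            except ValueError as exc:
                block[f"{a}_vs_{b}"] = {"error": str(exc)}
        if by_stream and "target_stream" in cells.columns:
            for stream, sub in cells.groupby("target_stream", observed=True):
                wide_s = sub.pivot(
                    index="participant", columns="cue_condition", values=measure
                )
                for a, b in _CONTRAST_PAIRS:
                    pair = wide_s[[a, b]].dropna()
                    try:
                        res = paired_ttest(pair[a].to_numpy(), pair[b].to_numpy())
                        block[f"{a}_vs_{b}_stream_{stream}"] = {
                            "t": res.t,
                            "df": res.df,
                            "p": res.p,
                        }
                    except ValueError as exc:
                        block[f"{a}_vs_{b}_stream_{stream}"] = {"error": str(exc)}
        out[measure] = block
    return out


def _run_anovas(cells: pd.DataFrame, experiment: str) -> dict:
    out: dict = {}
    for measure in _MEASURES:
        if experiment == "exp1":
            data = cells.rename(
                columns={"cue_condition": "A", "target_stream": "B", measure: "value"}
            )[["participant", "A", "B", "value"]].dropna()
            res = rm_anova(data, "twoway_rm")
        else:
            data = cells.rename(columns={"cue_condition": "A", measure: "value"})[
                ["participant", "A", "value"]
            ].dropna()
            res = rm_anova(data, "oneway_rm")
        out[measure] = {
            "design": res.design,
            "effects": {
                k: v for k, v in res.effects.items() if k != "subject"
            },
        }
    return out


def _render_participant_audio(
    design: pd.DataFrame, dcfg: DesignConfig, out_dir: Path, n_trials: int
) -> list[Path]:
    """Render the first ``n_trials`` trials of a design to WAV + annotation CSV."""
    out_dir.mkdir(parents=True, exist_ok=True)
    scfg = dcfg.stimulus
    written: list[Path] = []
    for _, row in design.head(n_trials).iterrows():
        seed = int(row.stimulus_seed)
        dur = scfg.source_duration + 1.0  # headroom for the central cut
        src_a = synth_speechlike(SourceSpec("speechlike", dur, seed=seed + 1, rate=scfg.sample_rate))
        kind_b = "speechlike" if dcfg.mode == "speech_speech" else "envlike"
        maker_b = synth_speechlike if kind_b == "speechlike" else synth_envlike
        src_b = maker_b(SourceSpec(kind_b, dur, seed=seed + 2, rate=scfg.sample_rate))
        stim = build_trial_stimulus(
            src_a, src_b, row.target_stream, dcfg.mode, scfg, seed=seed
        )
        wav_path = out_dir / f"trial_{int(row.trial_id):04d}.wav"
        write_wav(wav_path, stim.mix)
        annot_path = out_dir / f"trial_{int(row.trial_id):04d}_annotation.csv"
        ann = stim.annotation
        pd.DataFrame(
            [
                {
                    "stimulus_id": int(row.trial_id),
                    "cut_sample": ann.cut_sample,
                    "first_onset": ann.first_onset,
                    "second_onset": ann.second_onset,
                    "rep_length": ann.rep_length,
                    "ramp_samples": ann.ramp_samples,
                }
            ]
        ).to_csv(annot_path, index=False)
        written += [wav_path, annot_path]
    return written


def run_experiment(cfg: RunConfig) -> ExperimentResult:
    """Run a full simulated experiment; write artifacts if an output dir is set."""
    seeds = participant_seeds(cfg.master_seed, cfg.n_participants)
    grouping = _grouping(cfg.experiment)

    designs: dict[int, pd.DataFrame] = {}
    responses: dict[int, pd.DataFrame] = {}
    scored: dict[int, pd.DataFrame] = {}
    files: list[Path] = []
    out_dir = Path(cfg.output_dir) if cfg.output_dir is not None else None

    for pid, seed in enumerate(seeds):
        dcfg = _base_design(cfg, seed)
        design = generate_design(dcfg)
        params = _base_observer(cfg, seed)
        resp = simulate_observer(design, params)
        designs[pid] = design
        responses[pid] = resp
        scored[pid] = score_trials(design, resp, params.stream_duration)
        if out_dir is not None:
            pdir = out_dir / f"participant_{pid:02d}"
            pdir.mkdir(parents=True, exist_ok=True)
            write_design_csv(design, pdir / "design.csv")
            write_responses_csv(resp, pdir / "responses.csv")
            files += [pdir / "design.csv", pdir / "responses.csv"]
            if cfg.render_audio:
                files += _render_participant_audio(
                    design, dcfg, pdir / "audio", cfg.n_rendered_trials
                )

    summary = summarize_experiment(scored, grouping)
    cells = _cell_means(scored, grouping)
    stats = {
        "experiment": cfg.experiment,
        "n_participants": cfg.n_participants,
        "master_seed": cfg.master_seed,
        "anova": _run_anovas(cells, cfg.experiment),
        "contrasts": _run_contrasts(cells, by_stream=cfg.experiment == "exp1"),
    }

    manifest = None
    if out_dir is not None:
        summary_path = out_dir / "summary.csv"
        summary.to_csv(summary_path, index=False)
        stats_path = out_dir / "stats.json"
        stats_path.write_text(json.dumps(stats, indent=2, default=float))
        files += [summary_path, stats_path]
        manifest = {
            "master_seed": cfg.master_seed,
            "files": {
                str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(files)
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ExperimentResult(
        config=cfg,
        designs=designs,
        responses=responses,
        scored=scored,
        summary=summary,
        per_participant_cells=cells,
        stats=stats,
        manifest=manifest,
    )
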