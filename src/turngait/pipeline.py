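"""End-to-end orchestration: synthesize or load trials, detect events,
segment the turn, extract spatiotemporal parameters, aggregate per subject
x condition, and run the Bayesian effect analysis — all from one config
with a single seed."""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from ._signal import DEFAULT_CUTOFF_HZ
from .bayes import ModelSpec, analyze_parameter
from .events import detect_events
from .io import (TrialRecording, read_csv_trajectories, read_trc, write_json,
                 write_results_table, write_trc)
from .spatiotemporal import TurnParameters, turn_parameters
from .synthetic import CohortDesign, CohortTrial, generate_cohort
from .turns import TURN_RATE_THRESHOLD, detect_turn

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``mode='synthesize'`` generates a cohort from ``design`` and analyzes
    it; ``mode='analyze'`` reads every TRC/CSV trajectory under
    ``input_dir`` (subject/condition taken from file metadata or sidecars).
    """

    mode: Literal["synthesize", "analyze"] = "synthesize"
    out_dir: str = "turngait_run"
    seed: int | None = None
    input_dir: str | None = None
    design: CohortDesign = field(default_factory=CohortDesign)
    turn_threshold: float = TURN_RATE_THRESHOLD
    filter_cutoff: float = DEFAULT_CUTOFF_HZ
    mcmc_chains: int = 4
    mcmc_draws: int = 5000
    mcmc_warmup: int = 500
    analyze_variability: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthesize", "analyze"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.mode == "analyze" and not self.input_dir:
            raise ValueError("mode='analyze' requires input_dir")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "design" in raw and isinstance(raw["design"], dict):
            d = dict(raw["design"])
            if "conditions" in d:
                d["conditions"] = [tuple(c) for c in d["conditions"]]
            raw["design"] = CohortDesign(**d)
        return cls(**raw)


def analyze_recording(recording: TrialRecording,
                      turn_threshold: float = TURN_RATE_THRESHOLD,
                      cutoff: float = DEFAULT_CUTOFF_HZ) -> TurnParameters:
    """Events -> turn segment -> spatiotemporal parameters for one trial."""
    events = detect_events(recording, cutoff)
    segment = detect_turn(recording, events, turn_threshold, cutoff=cutoff)
    return turn_parameters(recording, events, segment)


def _trial_rows(trials: list[CohortTrial], turn_threshold: float,
                cutoff: float) -> pd.DataFrame:
    rows = []
    for t in trials:
        try:
            events = detect_events(t.recording, cutoff)
            segment = detect_turn(t.recording, events, turn_threshold,
                                  cutoff=cutoff)
            tp = turn_parameters(t.recording, events, segment)
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for subject {t.subject}, condition "
                f"({t.speed_condition}, {t.amplitude}), trial {t.trial}") from exc
        row = {"subject": t.subject, "speed_condition": t.speed_condition,
               "amplitude": t.amplitude, "trial": t.trial,
               "turn_direction": segment.direction,
               "amplitude_measured": segment.amplitude_measured}
        row.update(tp.scalars())  # note: "speed" here is walking speed (m/s)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(trial_df: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition mean and within-subject SD of every
    parameter column (two-stage aggregation: trials were already averaged
    over their gait cycles)."""
    keys = ["subject", "speed_condition", "amplitude"]
    numeric = trial_df.select_dtypes("number").columns
    params = [c for c in numeric if c not in keys + ["trial"]]
    grouped = trial_df.groupby(keys)[params]
    mean = grouped.mean().add_suffix(":mean")
    sd = grouped.std(ddof=1).add_suffix(":sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def effects_report(summaries: pd.DataFrame, responses: list[str],
                   chains: int = 4, draws: int = 5000, warmup: int = 500,
                   seed: int | None = None) -> pd.DataFrame:
    """Fit the mixed model for each response column of the summary table
    and collect every contrast's posterior summary."""
    root = np.random.SeedSequence(seed)
    rows = []
    for response, seq in zip(responses, root.spawn(len(responses))):
        sub = summaries[["subject", "speed_condition", "amplitude", response]].dropna()
        if sub[response].nunique() < 2 or len(sub) < 8:
            log.warning("skipping %s: not enough data for inference", response)
            continue
        table = sub.rename(columns={response: "value",
                                    "speed_condition": "speed"})
        spec = ModelSpec(response=response, chains=chains, draws=draws,
                         warmup=warmup, seed=int(seq.generate_state(1)[0] % (2**31)))
        for est in analyze_parameter(table, spec):
            rows.append(est.to_row())
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute a full pipeline run; returns the manifest (also written to
    ``out_dir/manifest.json``).  Identical config + seed give identical
    outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    collected: list[str] = []

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if config.mode == "synthesize":
                design = dataclasses.replace(config.design, seed=config.seed)
                trials = generate_cohort(design)
            else:
                trials = _load_trials(Path(config.input_dir))
            trial_df = _trial_rows(trials, config.turn_threshold, config.filter_cutoff)
            trial_df.to_csv(out / "trial_parameters.csv", index=False)

            summaries = summarize_cohort(trial_df)
            summaries.to_csv(out / "subject_summaries.csv", index=False)

            responses = [c for c in summaries.columns if c.endswith(":mean")]
            if config.analyze_variability:
                responses += [c for c in summaries.columns if c.endswith(":sd")]
            effects = effects_report(summaries, responses,
                                     chains=config.mcmc_chains,
                                     draws=config.mcmc_draws,
                                     warmup=config.mcmc_warmup,
                                     seed=config.seed)
            write_results_table(effects, out / "effects_report.csv")
            collected = sorted({str(w.message) for w in caught
                                if issubclass(w.category, RuntimeWarning)})
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    manifest = {
        "turngait_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "n_trials": int(len(trial_df)),
        "n_subjects": int(trial_df["subject"].nunique()),
        "warnings": collected,
        "outputs": ["trial_parameters.csv", "subject_summaries.csv",
                    "effects_report.csv"],
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["design"]["conditions"] = [list(c) for c in echo["design"]["conditions"]]
    echo["design"]["condition_means"] = {
        p: {f"{s}@{a}": v for (s, a), v in table.items()}
        for p, table in echo["design"]["condition_means"].items()}
    return echo


def _load_trials(input_dir: Path) -> list[CohortTrial]:
    """Read every TRC/CSV trajectory under ``input_dir`` into pseudo cohort
    trials, taking subject/condition/trial from recording metadata."""
    trials: list[CohortTrial] = []
    files = sorted(list(input_dir.glob("*.trc")) + list(input_dir.glob("*.csv")))
    if not files:
        raise FileNotFoundError(f"no .trc or .csv trajectory files in {input_dir}")
    for i, path in enumerate(files):
        rec = read_trc(path) if path.suffix == ".trc" else read_csv_trajectories(path)
        meta = rec.metadata
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            import json
            meta.update(json.loads(sidecar.read_text()))
        trials.append(CohortTrial(
            subject=int(meta.get("subject", 0)),
            speed_condition=str(meta.get("speed_condition", "normal")),
            amplitude=int(float(meta.get("amplitude", 0)) or 0),
            trial=int(meta.get("trial", i)),
            scenario=None, recording=rec, ground_truth=None, realized={}))
    return trials


def write_cohort(trials: list[CohortTrial], out_dir: str | Path) -> list[Path]:
    """Write each trial as TRC plus a metadata/ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in trials:
        stem = f"s{t.subject:02d}_{t.speed_condition}_{t.amplitude:03d}_t{t.trial:02d}"
        trc = out / f"{stem}.trc"
        write_trc(t.recording, trc)
        sidecar = {
            "subject": t.subject, "speed_condition": t.speed_condition,
            "amplitude": t.amplitude, "trial": t.trial,
            "scenario": dataclasses.asdict(t.scenario) if t.scenario else None,
            "ground_truth": {
                "events": [dataclasses.asdict(e) for e in t.ground_truth.events]
                if t.ground_truth else None,
                "footfalls": [dataclasses.asdict(f) for f in t.ground_truth.footfalls]
                if t.ground_truth else None,
            },
        }
        write_json(sidecar, out / f"{stem}.meta.json")
        paths.append(trc)
    return paths
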