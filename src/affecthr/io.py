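"""File interchange: BIDS-style events TSV, beats CSV, patterns/BOLD TSV,
predictions and model tables, and the YAML run configuration.

Every writer's output is re-readable by the matching reader (round-trip
property); every reader enforces the domain-type invariants and names the
offending row/column in its error.  Unknown extra columns are preserved on
read where a frame is returned, otherwise ignored with a log line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mvpa import SVRHyperparams
from .sweep import DEFAULT_THRESHOLDS
from .synthetic import DEFAULT_RUN_LENGTH_S
from .types import (
    LIKERT_MAX,
    LIKERT_MIN,
    ActivationPatterns,
    BeatSeries,
    BOLDSeries,
    NormativeScore,
    StimulusSchedule,
    SubjectParams,
    Trial,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["onset", "duration", "trial_type", "valence_norm", "arousal_norm"]

__all__ = [
    "RunConfig",
    "write_events",
    "read_events",
    "write_beats",
    "read_beats",
    "write_patterns",
    "read_patterns",
    "write_bold",
    "read_bold",
    "write_scores",
    "read_scores",
]


# ---------------------------------------------------------------- events ---


def write_events(
    schedule: StimulusSchedule, scores: list[NormativeScore], outdir: str | Path
) -> list[Path]:
    """One BIDS-style events TSV per run: onset, duration, trial_type,
    valence_norm, arousal_norm."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    smap = {s.stimulus_id: s for s in scores}
    paths = []
    for run in range(schedule.n_runs):
        trials = schedule.run_trials(run)
        frame = pd.DataFrame(
            {
                "onset": [t.onset for t in trials],
                "duration": [t.duration for t in trials],
                "trial_type": [t.stimulus_id for t in trials],
                "valence_norm": [smap[t.stimulus_id].valence for t in trials],
                "arousal_norm": [smap[t.stimulus_id].arousal for t in trials],
            }
        )
        path = outdir / f"events_run{run}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def read_events(paths: list[str | Path]) -> tuple[StimulusSchedule, list[NormativeScore]]:
    """Read per-run events TSVs back into a schedule plus normative scores."""
    trials: list[Trial] = []
    scores: dict[int, NormativeScore] = {}
    for run, path in enumerate(paths):
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in frame.columns if c not in EVENT_COLUMNS]
        if extra:
            logger.info("%s: ignoring extra columns %s", path, extra)
        prev = -np.inf
        for i, row in frame.iterrows():
            if row["onset"] <= prev:
                raise ValueError(f"{path} row {i}: onset {row['onset']} not strictly increasing")
            prev = row["onset"]
            for col in ("valence_norm", "arousal_norm"):
                v = float(row[col])
                if not (LIKERT_MIN <= v <= LIKERT_MAX):
                    raise ValueError(
                        f"{path} row {i}: {col}={v} outside [{LIKERT_MIN}, {LIKERT_MAX}]"
                    )
            sid = int(row["trial_type"])
            trials.append(Trial(sid, run, float(row["onset"]), float(row["duration"])))
            score = NormativeScore(sid, float(row["valence_norm"]), float(row["arousal_norm"]))
            if sid in scores and scores[sid] != score:
                raise ValueError(f"{path} row {i}: conflicting scores for stimulus {sid}")
            scores[sid] = score
    schedule = StimulusSchedule(trials, n_runs=len(paths))
    return schedule, [scores[sid] for sid in sorted(scores)]


# ---------------------------------------------------------------- scores ---


def write_scores(scores: list[NormativeScore], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "stimulus_id": [s.stimulus_id for s in scores],
            "valence": [s.valence for s in scores],
            "arousal": [s.arousal for s in scores],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_scores(path: str | Path) -> list[NormativeScore]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        NormativeScore(int(r.stimulus_id), float(r.valence), float(r.arousal))
        for r in frame.itertuples()
    ]


# ----------------------------------------------------------------- beats ---


def write_beats(series: list[BeatSeries], path: str | Path) -> Path:
    """Two-column CSV (run, beat_time_s) for one subject."""
    path = Path(path)
    rows = []
    for s in series:
        for t in s.beat_times:
            rows.append({"run": s.run, "beat_time_s": t})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_beats(path: str | Path, subject_id: int = -1) -> list[BeatSeries]:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("run", "beat_time_s"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for run, grp in frame.groupby("run", sort=True):
        out.append(BeatSeries(subject_id, int(run), grp["beat_time_s"].to_numpy(dtype=float)))
    return out


# -------------------------------------------------------------- patterns ---


def write_patterns(patterns: ActivationPatterns, path: str | Path) -> Path:
    """TSV: first column stimulus_id, then one column per feature id."""
    path = Path(path)
    n_feat = patterns.matrix.shape[1]
    frame = pd.DataFrame(patterns.matrix, columns=[f"f{j}" for j in range(n_feat)])
    frame.insert(0, "stimulus_id", patterns.stimulus_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_patterns(path: str | Path, subject_id: int = -1) -> ActivationPatterns:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "stimulus_id" not in frame.columns:
        raise ValueError(f"{path}: missing column 'stimulus_id'")
    ids = frame["stimulus_id"].astype(int).tolist()
    matrix = frame.drop(columns="stimulus_id").to_numpy(dtype=float)
    return ActivationPatterns(subject_id, matrix, ids)


# ------------------------------------------------------------------ bold ---


def write_bold(series: BOLDSeries, path: str | Path) -> tuple[Path, Path]:
    """TSV (volumes x features) plus a JSON sidecar holding tr and run."""
    path = Path(path)
    n_feat = series.matrix.shape[1]
    pd.DataFrame(series.matrix, columns=[f"f{j}" for j in range(n_feat)]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"tr": series.tr, "run": series.run, "subject_id": series.subject_id})
    )
    return path, sidecar


def read_bold(path: str | Path) -> BOLDSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    matrix = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(dtype=float)
    return BOLDSeries(int(meta["subject_id"]), int(meta["run"]), matrix, float(meta["tr"]))


# ---------------------------------------------------------------- config ---


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    n_subjects: int = 50
    n_stim: int = 90
    n_runs: int = 2
    n_features: int = 200
    presentation_s: float = 2.0
    iti_range: tuple[float, float] = (2.0, 6.0)
    run_length_s: float = DEFAULT_RUN_LENGTH_S
    seed: int = 0
    outdir: str = "run_output"
    use_beta_series: bool = False
    tr: float = 2.0
    bold_noise_sd: float = 0.0
    use_random: str = "lrt"  # random-effects policy for effect sizes
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    subject_params: dict = field(default_factory=dict)  # SubjectParams overrides (cohort-wide)
    per_subject: dict = field(default_factory=dict)  # subject_id -> overrides
    svr: dict = field(default_factory=dict)  # SVRHyperparams overrides

    def subject(self, subject_id: int) -> SubjectParams:
        kwargs = dict(self.subject_params)
        kwargs.update(self.per_subject.get(subject_id, self.per_subject.get(str(subject_id), {})))
        return SubjectParams(subject_id=subject_id, **kwargs)

    def hyperparams(self) -> SVRHyperparams:
        return SVRHyperparams(**self.svr)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = dataclasses.asdict(self)
        raw["iti_range"] = list(self.iti_range)
        raw["thresholds"] = [float(t) for t in self.thresholds]
        path.write_text(yaml.safe_dump(raw, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "iti_range" in raw:
            raw["iti_range"] = tuple(raw["iti_range"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)
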