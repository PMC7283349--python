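"""Domain containers shared across the pipeline.

All containers are plain dataclasses over numpy arrays / pandas frames; they
validate their own invariants on construction so that file readers and
generators fail loudly at the boundary rather than deep inside a model fit.

Conventions
-----------
* Times are seconds; heart rate is beats per minute (bpm = 60 / IBI).
* Valence and arousal are normative Likert means on [1, 9]; 5 is neutral.
* The post-stimulus heart-rate-change time course has exactly 8 half-second
  bins spanning 0-4 s after stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BINS = 8
BIN_WIDTH = 0.5  # seconds
POST_WINDOW = 4.0  # seconds post-onset covered by the bins
PRE_WINDOW = 1.0  # seconds pre-onset used for the baseline
VALENCE_MID = 5.0
LIKERT_MIN, LIKERT_MAX = 1.0, 9.0


class InvariantError(ValueError):
    """A domain-type invariant was violated."""


@dataclass(frozen=True)
class Trial:
    stimulus_id: int
    run: int
    onset: float
    duration: float


@dataclass
class StimulusSchedule:
    """Timed trial list: which stimulus appears when, in which run."""

    trials: list[Trial]
    n_runs: int
    presentation_s: float = 2.0
    iti_range: tuple[float, float] = (2.0, 6.0)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise InvariantError("n_runs must be >= 1")
        for run in range(self.n_runs):
            onsets = [t.onset for t in self.trials if t.run == run]
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise InvariantError(f"onsets not strictly increasing in run {run}")
        for t in self.trials:
            if t.duration <= 0:
                raise InvariantError(f"non-positive duration for stimulus {t.stimulus_id}")

    @property
    def stimulus_ids(self) -> list[int]:
        return [t.stimulus_id for t in self.trials]

    def run_trials(self, run: int) -> list[Trial]:
        return [t for t in self.trials if t.run == run]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset for t in self.trials],
                "duration": [t.duration for t in self.trials],
                "trial_type": [t.stimulus_id for t in self.trials],
                "run": [t.run for t in self.trials],
            }
        )


@dataclass(frozen=True)
class NormativeScore:
    """Normative affect rating of one stimulus (9-point Likert means)."""

    stimulus_id: int
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (LIKERT_MIN <= v <= LIKERT_MAX):
                raise InvariantError(
                    f"{name}={v} outside [{LIKERT_MIN}, {LIKERT_MAX}] "
                    f"for stimulus {self.stimulus_id}"
                )


def scores_frame(scores: list[NormativeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stimulus_id": [s.stimulus_id for s in scores],
            "valence": [s.valence for s in scores],
            "arousal": [s.arousal for s in scores],
        }
    )


def valence_map(scores: list[NormativeScore]) -> dict[int, float]:
    ids = [s.stimulus_id for s in scores]
    if len(set(ids)) != len(ids):
        raise InvariantError("duplicate stimulus_id in score list")
    return {s.stimulus_id: s.valence for s in scores}


@dataclass
class SubjectParams:
    """Per-subject generative parameters for the synthetic cohort.

    decel_gain_neg/pos are bpm of peak deceleration per Likert unit of
    distance from the neutral midpoint; perceived_divergence_sd0 controls how
    strongly a subject's perceived valence diverges from the normative score
    for neutral stimuli (the divergence shrinks linearly to zero at the
    Likert poles).
    """

    subject_id: int = 0
    baseline_ibi: float = 0.85
    ibi_noise_sd: float = 0.01
    decel_gain_neg: float = 1.0
    decel_gain_pos: float = 0.0
    triphasic: bool = False
    kernel_peak_time: float = 2.0
    encoding_shared_weight: float = 1.0
    encoding_idiosyncrasy_sd: float = 0.0
    perceived_divergence_sd0: float = 0.0
    activation_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_ibi <= 0.3:
            raise InvariantError("baseline_ibi must exceed 0.3 s")
        for name in (
            "ibi_noise_sd",
            "encoding_idiosyncrasy_sd",
            "perceived_divergence_sd0",
            "activation_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")


@dataclass
class BeatSeries:
    """Strictly increasing heart-beat times (s) for one subject/run."""

    subject_id: int
    run: int
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1:
            raise InvariantError("beat_times must be 1-D")
        if np.any(np.diff(self.beat_times) <= 0):
            raise InvariantError("beat_times must be strictly increasing")


@dataclass
class BOLDSeries:
    """Volumes x features signal matrix for one subject/run, sampled at tr."""

    subject_id: int
    run: int
    matrix: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.tr <= 0:
            raise InvariantError("tr must be positive")
        if not np.all(np.isfinite(self.matrix)):
            raise InvariantError("BOLD matrix contains non-finite values")


@dataclass
class ActivationPatterns:
    """Per-stimulus activation feature vectors (stimuli x features)."""

    subject_id: int
    matrix: np.ndarray
    stimulus_ids: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.stimulus_ids):
            raise InvariantError("row count must equal stimulus count")
        if not np.all(np.isfinite(self.matrix)):
            raise InvariantError("activation matrix contains non-finite values")


@dataclass
class IBISeries:
    """Inter-beat intervals, each assigned to the time of its second beat."""

    times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.times.shape != self.intervals.shape:
            raise InvariantError("times and intervals must have equal length")
        if np.any(self.intervals <= 0):
            raise InvariantError("intervals must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise InvariantError("IBI times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HRChangeTimecourse:
    """Eight half-second bins of bpm change vs the pre-stimulus baseline."""

    stimulus_id: int
    subject_id: int
    baseline_bpm: float | None
    bins: np.ndarray = field(default_factory=lambda: np.full(N_BINS, np.nan))
    bin_valid: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, bool))

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.bin_valid = np.asarray(self.bin_valid, dtype=bool)
        if self.bins.shape != (N_BINS,) or self.bin_valid.shape != (N_BINS,):
            raise InvariantError(f"exactly {N_BINS} bins required")
        if self.baseline_bpm is not None and self.baseline_bpm <= 0:
            raise InvariantError("baseline_bpm must be positive when present")

    @property
    def baseline_missing(self) -> bool:
        return self.baseline_bpm is None


@dataclass
class GroupTimecourse:
    """Per-stimulus subject-mean HR-change trajectory."""

    stimulus_id: int
    mean_bins: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.mean_bins = np.asarray(self.mean_bins, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if self.mean_bins.shape != (N_BINS,):
            raise InvariantError(f"exactly {N_BINS} mean bins required")
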