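"""Beta-series estimation: one hemodynamic regressor per stimulus.

A single GLM gives every stimulus its own regressor (its presentation boxcar
convolved with the canonical double-gamma HRF) plus per-run Legendre drift
polynomials; the OLS coefficient of each stimulus regressor is that
stimulus's activation, so solving the GLM for every feature column yields
the stimuli x features activation-pattern matrix used for decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import linalg

from .hrf import boxcar_hrf_regressor
from .types import ActivationPatterns, BOLDSeries, StimulusSchedule

__all__ = ["DesignMatrix", "build_design_matrix", "fit_betas"]


@dataclass
class DesignMatrix:
    """Concatenated-run design: stimulus columns first, then nuisance."""

    matrix: np.ndarray
    column_labels: list[str]
    stimulus_ids: list[int]
    n_vols_per_run: int
    n_runs: int

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)


def _legendre_drift(n_vols: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_vols)
    cols = []
    for p in range(order + 1):
        coef = np.zeros(p + 1)
        coef[p] = 1.0
        cols.append(legendre.legval(x, coef))
    return np.column_stack(cols)


def build_design_matrix(
    schedule: StimulusSchedule,
    n_vols_per_run: int,
    tr: float,
    drift_order: int = 2,
    extra_nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """One HRF-convolved boxcar column per stimulus, runs concatenated.

    Stimulus columns are ordered by sorted stimulus id (the interchange
    order used by every patterns file).  Drift columns are Legendre
    polynomials up to ``drift_order`` per run; ``drift_order=0`` leaves a
    per-run intercept only.  ``extra_nuisance`` (total volumes x k, e.g.
    motion regressors loaded from file) is appended unchanged.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if drift_order < 0:
        raise ValueError("drift_order must be >= 0")
    run_end = n_vols_per_run * tr
    for t in schedule.trials:
        if t.onset + t.duration + 16.0 > run_end:
            raise ValueError(
                f"insufficient volumes: trial stimulus={t.stimulus_id} run={t.run} "
                f"onset={t.onset:.2f}s needs coverage to {t.onset + t.duration + 16.0:.2f}s "
                f"but run ends at {run_end:.2f}s"
            )
    stim_ids = sorted(set(schedule.stimulus_ids))
    col_of = {sid: j for j, sid in enumerate(stim_ids)}
    vol_times = np.arange(n_vols_per_run) * tr
    n_total = n_vols_per_run * schedule.n_runs

    stim_block = np.zeros((n_total, len(stim_ids)))
    for run in range(schedule.n_runs):
        rows = slice(run * n_vols_per_run, (run + 1) * n_vols_per_run)
        for trial in schedule.run_trials(run):
            stim_block[rows, col_of[trial.stimulus_id]] = boxcar_hrf_regressor(
                vol_times, trial.onset, trial.duration
            )

    drift_cols = []
    drift_labels = []
    per_run_drift = _legendre_drift(n_vols_per_run, drift_order)
    for run in range(schedule.n_runs):
        block = np.zeros((n_total, drift_order + 1))
        block[run * n_vols_per_run : (run + 1) * n_vols_per_run, :] = per_run_drift
        drift_cols.append(block)
        drift_labels += [f"drift_run{run}_p{p}" for p in range(drift_order + 1)]
    nuisance = np.hstack(drift_cols)
    labels = [f"stim_{sid}" for sid in stim_ids] + drift_labels

    if extra_nuisance is not None:
        extra_nuisance = np.asarray(extra_nuisance, dtype=float)
        if extra_nuisance.shape[0] != n_total:
            raise ValueError(
                f"extra_nuisance has {extra_nuisance.shape[0]} rows, expected {n_total}"
            )
        nuisance = np.hstack([nuisance, extra_nuisance])
        labels += [f"nuisance_{k}" for k in range(extra_nuisance.shape[1])]

    return DesignMatrix(
        np.hstack([stim_block, nuisance]), labels, stim_ids, n_vols_per_run, schedule.n_runs
    )


def _rank_deficient_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    # QR with column pivoting: columns pivoted past the numerical rank are
    # the ones involved in the deficiency.
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    return [labels[j] for j in piv[rank:]]


def fit_betas(bold: list[BOLDSeries], design: DesignMatrix) -> ActivationPatterns:
    """Per-feature OLS over the concatenated runs; nuisance betas discarded."""
    bold_sorted = sorted(bold, key=lambda b: b.run)
    Y = np.vstack([b.matrix for b in bold_sorted])
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"dimension mismatch: BOLD has {Y.shape[0]} volumes, design has {X.shape[0]} rows"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _rank_deficient_columns(X, design.column_labels)
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    betas = coef[: design.n_stimuli, :]
    return ActivationPatterns(bold_sorted[0].subject_id, betas, list(design.stimulus_ids))
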