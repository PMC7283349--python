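"""Intra-subject decoding of valence from activation patterns.

A linear epsilon-insensitive support-vector regression is trained within
each subject under leave-one-out cross-validation: the prediction for
stimulus j comes from a model fit on the other M-1 stimuli, so every
prediction is out-of-fold.  Hyperparameters are pinned to the widely used
reference defaults for this estimator family -- box constraint C = 1,
epsilon = IQR(y)/13.49 (a robust estimate of sigma/10), linear kernel, no
feature standardisation -- and are recorded with every fitted model so that
results are reproducible across ecosystems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .types import ActivationPatterns, NormativeScore, valence_map

__all__ = ["SVRHyperparams", "LinearModel", "PredictionSet", "fit_linear_svr", "loocv_predict", "encoding_weights"]


@dataclass(frozen=True)
class SVRHyperparams:
    box_constraint: float = 1.0
    epsilon: float | None = None  # None -> IQR(y) / 13.49
    standardize: bool = False
    tol: float = 1e-6

    def resolve_epsilon(self, y: np.ndarray) -> float:
        if self.epsilon is not None:
            return self.epsilon
        eps = float(stats.iqr(y)) / 13.49
        return eps if eps > 0 else 1e-6


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    hyperparams: SVRHyperparams
    feature_mean: np.ndarray | None = None  # set when standardize is on
    feature_sd: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_sd
        return X @ self.weights + self.bias


@dataclass
class PredictionSet:
    subject_id: int
    records: list[tuple[int, float, int]] = field(default_factory=list)
    """(stimulus_id, predicted_valence, fold_excluded_stimulus_id) triples."""

    def __post_init__(self) -> None:
        for sid, _, excl in self.records:
            if sid != excl:
                raise ValueError(
                    f"leakage: prediction for stimulus {sid} came from fold excluding {excl}"
                )

    def predictions(self) -> dict[int, float]:
        return {sid: pred for sid, pred, _ in self.records}


def fit_linear_svr(X: np.ndarray, y: np.ndarray, hyperparams: SVRHyperparams | None = None) -> LinearModel:
    """Fit a linear epsilon-SVR; exact deterministic solver, tol 1e-6."""
    hp = hyperparams or SVRHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    mean = sd = None
    if hp.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd
    eps = hp.resolve_epsilon(y)
    svr = SVR(kernel="linear", C=hp.box_constraint, epsilon=eps, tol=hp.tol)
    svr.fit(X, y)
    return LinearModel(svr.coef_.ravel().copy(), float(svr.intercept_[0]), hp, mean, sd)


def loocv_predict(
    patterns: ActivationPatterns,
    scores: list[NormativeScore],
    hyperparams: SVRHyperparams | None = None,
    feature_mask: np.ndarray | None = None,
    return_models: bool = False,
):
    """Leave-one-out cross-validated valence predictions for one subject.

    For each stimulus j the model is trained on the other M-1
    pattern/valence pairs and predicts j; ``feature_mask`` (boolean or index
    array, e.g. a per-subject grey-matter mask) restricts the feature set.
    """
    vmap = valence_map(scores)
    missing = [sid for sid in patterns.stimulus_ids if sid not in vmap]
    if missing:
        raise ValueError(f"patterns contain stimulus ids without scores: {missing[:5]}")
    M = len(patterns.stimulus_ids)
    if M < 3:
        raise ValueError("LOOCV needs at least 3 stimuli")
    X = patterns.matrix
    if feature_mask is not None:
        X = X[:, feature_mask]
    y = np.array([vmap[sid] for sid in patterns.stimulus_ids])

    records = []
    models = []
    for j in range(M):
        keep = np.ones(M, dtype=bool)
        keep[j] = False
        model = fit_linear_svr(X[keep], y[keep], hyperparams)
        pred = float(model.predict(X[j : j + 1])[0])
        records.append((patterns.stimulus_ids[j], pred, patterns.stimulus_ids[j]))
        if return_models:
            models.append(model)
    pset = PredictionSet(patterns.subject_id, records)
    return (pset, models) if return_models else pset


def encoding_weights(
    models: list[LinearModel], X: np.ndarray | None = None, transform: bool = False
) -> np.ndarray:
    """Per-feature summary of fold hyperplanes: mean raw weight.

    With ``transform=True`` the mean weight vector is mapped to an
    activation pattern, cov(X) @ w_mean rescaled to unit norm, which is the
    interpretable forward-model counterpart of a backward decoding weight.
    """
    if not models:
        raise ValueError("need at least one model")
    n_feat = len(models[0].weights)
    if any(len(m.weights) != n_feat for m in models):
        raise ValueError("inconsistent feature counts across fold models")
    w = np.mean([m.weights for m in models], axis=0)
    if transform:
        if X is None:
            raise ValueError("activation-pattern transform requires X")
        a = np.cov(np.asarray(X, dtype=float), rowvar=False) @ w
        norm = np.linalg.norm(a)
        return a / norm if norm > 0 else a
    return w
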