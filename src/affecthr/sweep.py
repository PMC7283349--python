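"""Neutral-stimulus exclusion sweep over stimulus-set polar-extremity.

The stimulus set spans the full valence axis, so there is no natural
demarcation of "positive" and "negative" stimuli.  The sweep controls this
directly: for each threshold t on a grid (default 0 to 3 in steps of 0.2),
stimuli with |valence - 5| < t are excluded, the survivors are labelled
positive (valence > 5) or negative, and the mixed-effects effect-size
analysis is repeated on the filtered table.  Per threshold the sweep
records the per-measure R^2 and fixed-effect significance, the class mean
valences and s.d.s, and the fraction of stimuli kept.

Boundary conventions: exclusion is strict (|v - 5| < t excluded, so
endpoint stimuli at exactly 5 +/- t are kept); stimuli at exactly valence 5
are always excluded because the midpoint partition cannot label them.
tps_max is computed once on the full set and reused across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import ALPHA, effect_size_r2
from .types import VALENCE_MID, NormativeScore

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 3.01, 0.2), 10))

__all__ = ["SweepRow", "stratify", "sweep", "DEFAULT_THRESHOLDS"]


@dataclass
class SweepRow:
    threshold: float
    n_kept: int
    fraction_kept: float
    mean_val_pos: float
    sd_val_pos: float
    mean_val_neg: float
    sd_val_neg: float
    r2_hr: float
    r2_svm: float
    sig_hr: bool
    sig_svm: bool
    estimable: bool = True


def stratify(
    scores: list[NormativeScore], threshold: float
) -> tuple[list[int], dict[int, str]]:
    """Kept stimulus ids and their polarity labels at one threshold."""
    if not (0.0 <= threshold <= 4.0):
        raise ValueError(f"threshold {threshold} outside [0, 4]")
    kept = []
    labels = {}
    for s in scores:
        if s.valence == VALENCE_MID or abs(s.valence - VALENCE_MID) < threshold:
            continue
        kept.append(s.stimulus_id)
        labels[s.stimulus_id] = "pos" if s.valence > VALENCE_MID else "neg"
    return kept, labels


def _class_stats(scores: list[NormativeScore], ids: list[int], labels: dict[int, str]):
    out = {}
    for cls in ("pos", "neg"):
        vals = [s.valence for s in scores if s.stimulus_id in labels and labels[s.stimulus_id] == cls]
        out[cls] = (
            (float(np.mean(vals)), float(np.std(vals, ddof=0))) if vals else (np.nan, np.nan)
        )
    return out


def sweep(
    table: pd.DataFrame,
    scores: list[NormativeScore],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    use_random: str = "lrt",
    alpha: float = ALPHA,
) -> list[SweepRow]:
    """Repeat the separate-mode effect-size analysis per exclusion threshold.

    Thresholds leaving fewer than 4 stimuli, only one polarity class, or too
    few rows to fit are emitted flagged not-estimable rather than dropped,
    preserving the grid shape.
    """
    if len(thresholds) == 0:
        raise ValueError("empty threshold list")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    n_base = len(scores)
    rows = []
    for t in thresholds:
        kept, labels = stratify(scores, float(t))
        stats = _class_stats(scores, kept, labels)
        n_classes = len(set(labels.values()))
        sub = table[table["stimulus_id"].isin(kept)]
        base = dict(
            threshold=float(t),
            n_kept=len(kept),
            fraction_kept=len(kept) / n_base,
            mean_val_pos=stats["pos"][0],
            sd_val_pos=stats["pos"][1],
            mean_val_neg=stats["neg"][0],
            sd_val_neg=stats["neg"][1],
        )
        if len(kept) < 4 or n_classes < 2:
            rows.append(
                SweepRow(**base, r2_hr=np.nan, r2_svm=np.nan, sig_hr=False, sig_svm=False,
                         estimable=False)
            )
            continue
        try:
            eff = effect_size_r2(
                sub, ["delta_hr", "svm_pred"], mode="separate", use_random=use_random, alpha=alpha
            )
        except ValueError:
            rows.append(
                SweepRow(**base, r2_hr=np.nan, r2_svm=np.nan, sig_hr=False, sig_svm=False,
                         estimable=False)
            )
            continue
        rows.append(
            SweepRow(
                **base,
                r2_hr=eff["delta_hr"].r2,
                r2_svm=eff["svm_pred"].r2,
                sig_hr=eff["delta_hr"].p_fixed < alpha,
                sig_svm=eff["svm_pred"].p_fixed < alpha,
            )
        )
    return rows


def sweep_frame(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
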