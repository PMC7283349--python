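"""Mixed-effects combination of the cardiac and neural valence measures.

The response is the normative valence score of each stimulus; the two
affective measures -- heart-rate change at tps_max (dHR) and the
out-of-fold SVR-predicted valence -- enter as fixed effects, with
subject-wise random intercept and slopes.  Models are fit by maximum
likelihood (not REML) so that nested models can be compared with a
likelihood-ratio test; only random effects that survive the LRT are
incorporated into effect-size estimates.  Effect sizes are residual-based:
R^2 = 1 - SS_res / SS_tot, with residuals conditional on the fitted random
effects (the reference mixed-model implementations' default residual).

The uniqueness analyses probe whether the two channels carry redundant or
complementary information: predicting one measure from the other, and
predicting each measure's calibration error from normative valence and from
the other measure's error.  "dHR-based prediction" of valence is the fitted
value of a valence ~ dHR linear calibration; its error is response minus
fitted value (and likewise for the SVR channel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.05

__all__ = [
    "GLMMSpec",
    "GLMMResult",
    "build_model_table",
    "fit_glmm",
    "lrt_random_effects",
    "effect_size_r2",
    "uniqueness_analysis",
]


@dataclass(frozen=True)
class GLMMSpec:
    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()  # subset of {"intercept"} | fixed
    grouping: str = "subject_id"

    def __post_init__(self) -> None:
        allowed = set(self.fixed) | {"intercept"}
        bad = [r for r in self.random if r not in allowed]
        if bad:
            raise ValueError(f"random terms {bad} not in fixed effects or intercept")

    def n_cov_params(self) -> int:
        q = len(self.random)
        return q * (q + 1) // 2


@dataclass
class GLMMResult:
    spec: GLMMSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: dict
    llf: float
    resid: np.ndarray
    r2: float
    n_obs: int
    converged: bool = True
    singular: bool = False

    def __post_init__(self) -> None:
        # r2 must be reproducible from the stored residuals and the response
        # sum of squares carried in cov_params["ss_tot"].
        ss_tot = self.cov_params.get("ss_tot")
        if ss_tot:
            recomputed = 1.0 - float(np.sum(self.resid**2)) / ss_tot
            if abs(recomputed - self.r2) > 1e-8:
                raise ValueError("stored r2 inconsistent with stored residuals")


def build_model_table(
    delta_hr_rows: list[tuple[int, int, float | None]],
    predictions: dict[int, dict[int, float]],
    valences: dict[int, float],
) -> pd.DataFrame:
    """Merge dHR values, SVR predictions and normative scores.

    ``delta_hr_rows`` holds (subject_id, stimulus_id, dHR-or-None);
    ``predictions`` maps subject -> stimulus -> predicted valence.  Rows
    with a missing response are impossible by construction; predictor
    missingness is kept as NaN and handled listwise by each fitted model.
    """
    rows = []
    n_missing = 0
    for subject_id, stimulus_id, dhr in delta_hr_rows:
        if dhr is None:
            n_missing += 1
            dhr = np.nan
        rows.append(
            {
                "subject_id": subject_id,
                "stimulus_id": stimulus_id,
                "valence_norm": valences[stimulus_id],
                "delta_hr": dhr,
                "svm_pred": predictions.get(subject_id, {}).get(stimulus_id, np.nan),
            }
        )
    if n_missing:
        logger.info("model table: %d trials with missing dHR (dropped listwise per fit)", n_missing)
    return pd.DataFrame(rows)


def _complete_rows(table: pd.DataFrame, spec: GLMMSpec) -> pd.DataFrame:
    cols = [spec.response, *spec.fixed, spec.grouping]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"model table lacks columns {missing}")
    return table.dropna(subset=cols)


def fit_glmm(table: pd.DataFrame, spec: GLMMSpec) -> GLMMResult:
    """ML fit of the specified fixed + subject-wise random effects.

    With no random terms this reduces to OLS (identical likelihood family),
    so likelihoods remain comparable across the nesting.  Fixed-effect
    p-values are single-coefficient tests of beta = 0.  A singular random
    effects covariance is reported via the ``singular`` flag, with the
    offending variance pinned at the boundary, not raised.
    """
    data = _complete_rows(table, spec)
    if len(data) < 10:
        raise ValueError(f"need >= 10 complete rows, got {len(data)}")
    y = data[spec.response].to_numpy(dtype=float)
    X = sm.add_constant(data[list(spec.fixed)].astype(float), has_constant="add")
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    if not spec.random:
        res = sm.OLS(y, X).fit()
        resid = np.asarray(res.resid)
        return GLMMResult(
            spec=spec,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            cov_params={"resid_var": float(res.scale), "ss_tot": ss_tot},
            llf=float(res.llf),
            resid=resid,
            r2=1.0 - float(np.sum(resid**2)) / ss_tot,
            n_obs=len(data),
        )

    if data[spec.grouping].nunique() < 2:
        raise ValueError("random effects need >= 2 grouping units")
    re_cols = []
    re_names = []
    for term in spec.random:
        if term == "intercept":
            re_cols.append(np.ones(len(data)))
        else:
            re_cols.append(data[term].to_numpy(dtype=float))
        re_names.append(term)
    exog_re = np.column_stack(re_cols)

    model = sm.MixedLM(y, X, groups=data[spec.grouping].to_numpy(), exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method=["lbfgs", "powell"])
    cov_re = np.asarray(res.cov_re)
    singular = bool(np.any(np.diag(cov_re) < 1e-8)) or not res.converged
    fe_names = list(X.columns)
    params = res.params[fe_names]
    try:
        resid = np.asarray(res.resid)  # conditional on fitted random effects
    except (ValueError, np.linalg.LinAlgError):
        # variance component pinned at the boundary: BLUPs are zero and the
        # conditional residual reduces to the marginal one
        singular = True
        resid = y - np.asarray(X, dtype=float) @ params.to_numpy()
    llf = float(res.llf)
    if not np.isfinite(llf):
        # optimiser pinned the covariance at exactly zero; the likelihood
        # there is the OLS likelihood, which statsmodels fails to report
        singular = True
        llf = float(sm.OLS(y, X).fit().llf)
    return GLMMResult(
        spec=spec,
        params=params,
        bse=res.bse[fe_names],
        pvalues=res.pvalues[fe_names],
        cov_params={
            "cov_re": cov_re,
            "re_names": re_names,
            "resid_var": float(res.scale),
            "ss_tot": ss_tot,
        },
        llf=llf,
        resid=resid,
        r2=1.0 - float(np.sum(resid**2)) / ss_tot,
        n_obs=len(data),
        converged=bool(res.converged),
        singular=singular,
    )


def lrt_random_effects(
    table: pd.DataFrame,
    spec_full: GLMMSpec,
    spec_reduced: GLMMSpec,
    boundary_mixture: bool = False,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the extra random effects in ``spec_full``.

    statistic = 2 (LL_full - LL_reduced) clipped at zero; df = difference in
    covariance-parameter count; reference distribution plain chi-square
    (conservative at the variance boundary) or, with ``boundary_mixture``,
    the 50:50 chi-square mixture of df and df-1.
    """
    if spec_full.fixed != spec_reduced.fixed or spec_full.response != spec_reduced.response:
        raise ValueError("LRT specs must share response and fixed effects")
    if not set(spec_reduced.random) <= set(spec_full.random):
        raise ValueError("reduced random effects not nested in full")
    full = fit_glmm(table, spec_full)
    reduced = fit_glmm(table, spec_reduced)
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = spec_full.n_cov_params() - spec_reduced.n_cov_params()
    if df == 0:
        return stat, 0, 1.0
    if boundary_mixture:
        p_hi = stats.chi2.sf(stat, df)
        p_lo = stats.chi2.sf(stat, df - 1) if df > 1 else (1.0 if stat <= 0 else 0.0)
        p = 0.5 * (p_hi + p_lo)
    else:
        p = stats.chi2.sf(stat, df)
    return stat, df, float(p)


@dataclass
class EffectSize:
    measure: str
    r2: float
    p_fixed: float
    beta: float
    used_random: bool
    mode: str = "separate"


def _spec_pair(response: str, fixed: tuple[str, ...], grouping: str) -> tuple[GLMMSpec, GLMMSpec]:
    full = GLMMSpec(response, fixed, ("intercept", *fixed), grouping)
    reduced = GLMMSpec(response, fixed, (), grouping)
    return full, reduced


def _fit_with_random_policy(
    table: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...],
    use_random: str,
    grouping: str = "subject_id",
    alpha: float = ALPHA,
) -> tuple["GLMMResult", bool]:
    full, reduced = _spec_pair(response, fixed, grouping)
    if use_random == "none":
        return fit_glmm(table, reduced), False
    if use_random == "always":
        return fit_glmm(table, full), True
    if use_random != "lrt":
        raise ValueError(f"unknown use_random policy {use_random!r}")
    _, _, p = lrt_random_effects(table, full, reduced)
    if p < alpha:
        return fit_glmm(table, full), True
    return fit_glmm(table, reduced), False


def effect_size_r2(
    table: pd.DataFrame,
    measures: list[str],
    mode: str = "separate",
    response: str = "valence_norm",
    use_random: str = "lrt",
    alpha: float = ALPHA,
) -> dict[str, EffectSize]:
    """Residual-based R^2 contribution per measure.

    ``separate`` (default): each measure's R^2 comes from its own
    single-fixed-effect model.  ``semipartial``: R^2 of the all-measures
    model minus R^2 of the model omitting that measure.  ``use_random``
    controls the random-effects policy: "lrt" keeps subject-wise random
    intercept+slope only when the likelihood-ratio test is significant,
    "none" and "always" force the choice.
    """
    if not measures:
        raise ValueError("measures must be non-empty")
    bad = [m for m in measures if m not in table.columns]
    if bad:
        raise ValueError(f"measures {bad} not in table")
    out: dict[str, EffectSize] = {}
    if mode == "separate":
        for m in measures:
            res, used = _fit_with_random_policy(table, response, (m,), use_random, alpha=alpha)
            out[m] = EffectSize(m, res.r2, float(res.pvalues[m]), float(res.params[m]), used, mode)
    elif mode == "semipartial":
        res_all, used = _fit_with_random_policy(
            table, response, tuple(measures), use_random, alpha=alpha
        )
        for m in measures:
            others = tuple(x for x in measures if x != m)
            if others:
                res_wo, _ = _fit_with_random_policy(table, response, others, use_random, alpha=alpha)
                r2_wo = res_wo.r2
            else:
                r2_wo = 0.0
            out[m] = EffectSize(
                m, res_all.r2 - r2_wo, float(res_all.pvalues[m]), float(res_all.params[m]), used, mode
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def uniqueness_analysis(
    table: pd.DataFrame, use_random: str = "lrt", alpha: float = ALPHA
) -> dict[str, GLMMResult]:
    """The four cross-channel models probing unique information content.

    (a) svm_pred ~ delta_hr; (b) SVR calibration error ~ valence_norm;
    (c) dHR calibration error ~ valence_norm; (d) SVR error ~ dHR error.
    Each measure's calibration error is response - fitted value of an OLS
    valence ~ measure calibration, computed on listwise-complete rows.
    """
    data = table.dropna(subset=["valence_norm", "delta_hr", "svm_pred"]).copy()
    for col in ("delta_hr", "svm_pred"):
        if np.isclose(data[col].std(), 0.0):
            raise ValueError(f"degenerate constant column {col!r}")
    for measure, err_col in (("delta_hr", "err_hr"), ("svm_pred", "err_svm")):
        X = sm.add_constant(data[[measure]].astype(float))
        fit = sm.OLS(data["valence_norm"].to_numpy(dtype=float), X).fit()
        data[err_col] = data["valence_norm"].to_numpy(dtype=float) - np.asarray(fit.fittedvalues)

    specs = {
        "svm_on_hr": ("svm_pred", ("delta_hr",)),
        "svm_err_on_valence": ("err_svm", ("valence_norm",)),
        "hr_err_on_valence": ("err_hr", ("valence_norm",)),
        "svm_err_on_hr_err": ("err_svm", ("err_hr",)),
    }
    out = {}
    for name, (response, fixed) in specs.items():
        res, _ = _fit_with_random_policy(data, response, fixed, use_random, alpha=alpha)
        out[name] = res
    return out
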