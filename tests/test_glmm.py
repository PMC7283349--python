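"""Mixed-effects modeling: fits, LRT, effect sizes, uniqueness analyses."""

import numpy as np
import pandas as pd
import pytest

from affecthr import glmm


def make_table(n_subj=12, n_stim=40, beta_svm=0.5, beta_hr=-0.05, re_int_sd=0.0,
               re_slope_sd=0.0, noise_sd=1.0, seed=0):
    """Direct generative model for a model table with known coefficients."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        b0 = rng.normal(0, re_int_sd) if re_int_sd > 0 else 0.0
        b1 = rng.normal(0, re_slope_sd) if re_slope_sd > 0 else 0.0
        svm = rng.normal(0, 2, n_stim)
        dhr = rng.normal(0, 4, n_stim)
        y = 5.0 + b0 + (beta_svm + b1) * svm + beta_hr * dhr + rng.normal(0, noise_sd, n_stim)
        y = np.clip(y, 1, 9)
        for j in range(n_stim):
            rows.append({"subject_id": s, "stimulus_id": j, "valence_norm": y[j],
                         "delta_hr": dhr[j], "svm_pred": svm[j]})
    return pd.DataFrame(rows)


class TestFitGlmm:
    def test_no_random_terms_matches_ols_closed_form(self):
        table = make_table(seed=1)
        spec = glmm.GLMMSpec("valence_norm", ("delta_hr", "svm_pred"))
        res = glmm.fit_glmm(table, spec)
        X = np.column_stack([np.ones(len(table)), table["delta_hr"], table["svm_pred"]])
        beta, *_ = np.linalg.lstsq(X, table["valence_norm"].to_numpy(), rcond=None)
        np.testing.assert_allclose(
            res.params[["const", "delta_hr", "svm_pred"]].to_numpy(), beta, atol=1e-6
        )

    def test_perfect_fit_gives_unit_slope_and_r2(self):
        table = make_table(seed=2)
        table["svm_pred"] = table["valence_norm"]
        res = glmm.fit_glmm(table, glmm.GLMMSpec("valence_norm", ("svm_pred",)))
        assert res.params["svm_pred"] == pytest.approx(1.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_mixed_fit_recovers_random_intercept_structure(self):
        table = make_table(n_subj=20, n_stim=40, re_int_sd=1.0, noise_sd=0.5, seed=3)
        spec = glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept",))
        res = glmm.fit_glmm(table, spec)
        var = res.cov_params["cov_re"][0, 0]
        assert 0.3 < var < 3.0
        assert res.params["svm_pred"] == pytest.approx(0.5, abs=0.1)

    def test_too_few_rows_raises(self):
        table = make_table(n_subj=1, n_stim=5)
        with pytest.raises(ValueError, match=">= 10"):
            glmm.fit_glmm(table, glmm.GLMMSpec("valence_norm", ("svm_pred",)))

    def test_invalid_random_term_rejected(self):
        with pytest.raises(ValueError, match="random terms"):
            glmm.GLMMSpec("valence_norm", ("svm_pred",), ("delta_hr",))

    def test_monotone_nesting_of_likelihood(self):
        table = make_table(n_subj=10, n_stim=30, re_int_sd=0.3, seed=4)
        base = glmm.fit_glmm(table, glmm.GLMMSpec("valence_norm", ("svm_pred",)))
        full = glmm.fit_glmm(
            table, glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept", "svm_pred"))
        )
        assert full.llf >= base.llf - 1e-6

    def test_r2_invariant_to_predictor_rescaling(self):
        table = make_table(seed=5)
        r1 = glmm.fit_glmm(table, glmm.GLMMSpec("valence_norm", ("svm_pred",))).r2
        table2 = table.copy()
        table2["svm_pred"] = 100.0 * table2["svm_pred"] + 7.0
        r2 = glmm.fit_glmm(table2, glmm.GLMMSpec("valence_norm", ("svm_pred",))).r2
        assert r2 == pytest.approx(r1, abs=1e-6)


class TestLrt:
    def test_identical_specs_give_zero_statistic(self):
        table = make_table(seed=6)
        spec = glmm.GLMMSpec("valence_norm", ("svm_pred",))
        stat, df, p = glmm.lrt_random_effects(table, spec, spec)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_non_nested_specs_raise(self):
        full = glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept",))
        other = glmm.GLMMSpec("valence_norm", ("delta_hr",))
        table = make_table()
        with pytest.raises(ValueError, match="share response and fixed"):
            glmm.lrt_random_effects(table, full, other)

    def test_large_random_slopes_detected(self):
        table = make_table(n_subj=20, n_stim=40, re_int_sd=0.8, re_slope_sd=0.5,
                           noise_sd=0.5, seed=7)
        full = glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept", "svm_pred"))
        reduced = glmm.GLMMSpec("valence_norm", ("svm_pred",))
        stat, df, p = glmm.lrt_random_effects(table, full, reduced)
        assert df == 3
        assert p < 1e-4

    def test_null_rejection_conservative_at_boundary(self):
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            table = make_table(n_subj=8, n_stim=25, re_int_sd=0.0, seed=100 + rep)
            full = glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept",))
            reduced = glmm.GLMMSpec("valence_norm", ("svm_pred",))
            _, _, p = glmm.lrt_random_effects(table, full, reduced)
            rejections += p < 0.05
        assert rejections <= 3  # ~ alpha * n_reps plus slack; boundary test is conservative

    def test_boundary_mixture_halves_p_at_df1(self):
        table = make_table(n_subj=10, n_stim=30, re_int_sd=0.4, seed=8)
        full = glmm.GLMMSpec("valence_norm", ("svm_pred",), ("intercept",))
        reduced = glmm.GLMMSpec("valence_norm", ("svm_pred",))
        stat, df, p_plain = glmm.lrt_random_effects(table, full, reduced)
        _, _, p_mix = glmm.lrt_random_effects(table, full, reduced, boundary_mixture=True)
        if stat > 0:
            assert p_mix == pytest.approx(p_plain / 2.0, rel=1e-6)


class TestEffectSizes:
    def test_response_equals_measure_gives_unit_r2(self):
        table = make_table(seed=9)
        table["svm_pred"] = table["valence_norm"]
        eff = glmm.effect_size_r2(table, ["svm_pred"], use_random="none")
        assert eff["svm_pred"].r2 == pytest.approx(1.0, abs=1e-10)

    def test_independent_measure_has_negligible_r2(self):
        table = make_table(n_subj=50, n_stim=90, beta_svm=0.0, beta_hr=0.0, seed=10)
        eff = glmm.effect_size_r2(table, ["delta_hr"], use_random="none")
        assert eff["delta_hr"].r2 < 0.01  # n = 4500 null

    def test_separate_matches_ols_when_random_absent(self):
        table = make_table(seed=11)
        eff_lrt = glmm.effect_size_r2(table, ["svm_pred"], use_random="lrt")
        eff_none = glmm.effect_size_r2(table, ["svm_pred"], use_random="none")
        if not eff_lrt["svm_pred"].used_random:
            assert eff_lrt["svm_pred"].r2 == pytest.approx(eff_none["svm_pred"].r2, abs=1e-6)

    def test_semipartial_mode_attributes_unique_variance(self):
        table = make_table(n_subj=20, n_stim=60, beta_svm=0.5, beta_hr=0.0, seed=12)
        eff = glmm.effect_size_r2(table, ["delta_hr", "svm_pred"], mode="semipartial",
                                  use_random="none")
        assert eff["svm_pred"].r2 > 10 * max(eff["delta_hr"].r2, 1e-6)

    def test_empty_measures_raise(self):
        with pytest.raises(ValueError, match="non-empty"):
            glmm.effect_size_r2(make_table(), [], use_random="none")


class TestUniqueness:
    def test_identical_channels_make_model_a_perfect(self):
        table = make_table(seed=13)
        table["svm_pred"] = table["delta_hr"]
        res = glmm.uniqueness_analysis(table, use_random="none")
        assert res["svm_on_hr"].r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_raises(self):
        table = make_table(seed=14)
        table["delta_hr"] = 3.0
        with pytest.raises(ValueError, match="degenerate"):
            glmm.uniqueness_analysis(table, use_random="none")

    def test_shared_latent_couples_the_errors(self):
        # one latent perceived valence drives both channels -> their
        # calibration errors correlate (model d significant)
        rng = np.random.default_rng(15)
        rows = []
        for s in range(10):
            latent = rng.uniform(1, 9, 40)
            v = latent + rng.normal(0, 0.5, 40)  # normative ~ latent
            svm = latent + rng.normal(0, 0.8, 40)
            dhr = -2.0 * (latent - 5) + rng.normal(0, 1.0, 40)
            for j in range(40):
                rows.append({"subject_id": s, "stimulus_id": j,
                             "valence_norm": float(np.clip(v[j], 1, 9)),
                             "delta_hr": dhr[j], "svm_pred": svm[j]})
        res = glmm.uniqueness_analysis(pd.DataFrame(rows), use_random="none")
        assert res["svm_err_on_hr_err"].pvalues["err_hr"] < 0.05

    def test_independent_channel_noise_leaves_errors_uncoupled(self):
        # Both calibration errors contain the response's unexplained
        # variance, so they are intrinsically coupled unless each channel is
        # a high-fidelity measure of valence; the proper null therefore uses
        # near-perfect channels with independent channel noise, where each
        # error reduces to that channel's own noise.
        rng = np.random.default_rng(16)
        rejections = 0
        n_reps = 40
        for rep in range(n_reps):
            rows = []
            for s in range(10):
                v = rng.uniform(1, 9, 40)
                svm = v + rng.normal(0, 0.1, 40)
                dhr = -2.0 * (v - 5) + rng.normal(0, 0.2, 40)
                for j in range(40):
                    rows.append({"subject_id": s, "stimulus_id": j, "valence_norm": v[j],
                                 "delta_hr": dhr[j], "svm_pred": svm[j]})
            res = glmm.uniqueness_analysis(pd.DataFrame(rows), use_random="none")
            rejections += res["svm_err_on_hr_err"].pvalues["err_hr"] < 0.05
        assert rejections / n_reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps)
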