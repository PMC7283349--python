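"""Synthetic cohort generator: schedules, scores, beats, activations, BOLD."""

import numpy as np
import pytest

from affecthr import hr, synthetic
from affecthr.hrf import double_gamma
from affecthr.types import SubjectParams


class TestSchedule:
    def test_study_layout_90_stimuli_two_runs(self):
        sch = synthetic.make_schedule(90, 2, 2.0, (2.0, 6.0), seed=1)
        assert len(sch.trials) == 90
        assert len(sch.run_trials(0)) == 45 and len(sch.run_trials(1)) == 45
        assert all(t.duration == 2.0 for t in sch.trials)
        for run in range(2):
            onsets = np.array([t.onset for t in sch.run_trials(run)])
            gaps = np.diff(onsets) - 2.0
            assert np.all(gaps >= 2.0) and np.all(gaps <= 6.0)

    def test_degenerate_iti_gives_fixed_onsets(self):
        sch = synthetic.make_schedule(2, 1, 2.0, (4.0, 4.0), seed=5)
        assert [t.onset for t in sch.trials] == [0.0, 6.0]

    def test_determinism_and_seed_sensitivity(self):
        a = synthetic.make_schedule(20, 2, 2.0, (2.0, 6.0), seed=3)
        b = synthetic.make_schedule(20, 2, 2.0, (2.0, 6.0), seed=3)
        c = synthetic.make_schedule(20, 2, 2.0, (2.0, 6.0), seed=4)
        assert a.trials == b.trials
        assert a.trials != c.trials

    def test_non_divisible_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            synthetic.make_schedule(91, 2, 2.0, (2.0, 6.0), seed=0)

    def test_negative_duration_raises(self):
        with pytest.raises(ValueError):
            synthetic.make_schedule(4, 2, -1.0, (2.0, 6.0), seed=0)

    def test_run_assignment_balances_valence(self):
        scores = synthetic.sample_normative_scores(90, seed=2)
        sch = synthetic.make_schedule(90, 2, seed=2)
        vmap = {s.stimulus_id: s.valence for s in scores}
        means = [np.mean([vmap[t.stimulus_id] for t in sch.run_trials(r)]) for r in range(2)]
        assert abs(means[0] - means[1]) < 0.5


class TestScores:
    def test_span_and_bounds(self):
        scores = synthetic.sample_normative_scores(90, seed=0)
        v = np.array([s.valence for s in scores])
        assert v.min() < 2.0 and v.max() > 8.0
        assert np.all((v >= 1.0) & (v <= 9.0))
        a = np.array([s.arousal for s in scores])
        assert np.all((a >= 1.0) & (a <= 9.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_every_unit_band_populated_at_16(self, seed):
        scores = synthetic.sample_normative_scores(16, seed=seed)
        bands = {min(int(s.valence), 8) for s in scores}
        assert bands == set(range(1, 9))  # all 8 unit-width valence bands occupied

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            synthetic.sample_normative_scores(1, seed=0)

    def test_arousal_envelope_is_v_shaped(self):
        scores = synthetic.sample_normative_scores(200, seed=1)
        extreme = [s.arousal for s in scores if abs(s.valence - 5) > 3]
        neutral = [s.arousal for s in scores if abs(s.valence - 5) < 1]
        assert np.mean(extreme) > np.mean(neutral)


class TestPerceivedValence:
    def test_zero_divergence_is_identity(self):
        scores = synthetic.sample_normative_scores(30, seed=0)
        params = SubjectParams(perceived_divergence_sd0=0.0)
        pv = synthetic.perceived_valence(scores, params, seed=1)
        for s in scores:
            assert pv[s.stimulus_id] == s.valence

    def test_polar_extremes_anchored_exactly(self):
        from affecthr.types import NormativeScore

        scores = [NormativeScore(0, 1.0, 5.0), NormativeScore(1, 9.0, 5.0)]
        params = SubjectParams(perceived_divergence_sd0=2.0)
        pv = synthetic.perceived_valence(scores, params, seed=7)
        assert pv[0] == 1.0 and pv[1] == 9.0

    def test_monte_carlo_sd_at_midpoint(self):
        from affecthr.types import NormativeScore

        params = SubjectParams(perceived_divergence_sd0=1.0)
        scores = [NormativeScore(i, 5.0, 5.0) for i in range(10_000)]
        pv = synthetic.perceived_valence(scores, params, seed=3)
        eta = np.array([pv[i] - 5.0 for i in range(10_000)])
        assert np.std(eta) == pytest.approx(1.0, abs=0.03)

    def test_variance_profile_matches_closed_form(self):
        # sd_j = sd0 * max(0, 1 - |v - 5| / 4), Monte-Carlo at several valences
        from affecthr.types import NormativeScore

        params = SubjectParams(perceived_divergence_sd0=0.8)
        n = 4000
        for v in (2.0, 3.5, 5.0, 6.5, 8.0):
            scores = [NormativeScore(i, v, 5.0) for i in range(n)]
            pv = synthetic.perceived_valence(scores, params, seed=int(v * 10))
            eta = np.array([pv[i] - v for i in range(n)])
            expected = 0.8 * max(0.0, 1.0 - abs(v - 5.0) / 4.0)
            # 3 sd of the sd estimator ~ 3 * expected / sqrt(2n)
            assert np.std(eta) == pytest.approx(expected, abs=3 * expected / np.sqrt(2 * n) + 1e-9)


class TestBeats:
    def test_homogeneous_limit_is_exact_unit_rhythm(self):
        sch = synthetic.make_schedule(2, 1, 2.0, (4.0, 4.0), seed=0)
        params = SubjectParams(baseline_ibi=1.0, ibi_noise_sd=0.0, decel_gain_neg=0.0)
        [beats] = synthetic.simulate_beats(sch, {t.stimulus_id: 5.0 for t in sch.trials}, params,
                                           run_length_s=20.0, seed=0)
        np.testing.assert_allclose(beats.beat_times, np.arange(20.0), atol=1e-12)

    def test_determinism(self):
        sch = synthetic.make_schedule(4, 2, seed=1)
        pv = {t.stimulus_id: 3.0 for t in sch.trials}
        params = SubjectParams()
        a = synthetic.simulate_beats(sch, pv, params, run_length_s=60.0, seed=9)
        b = synthetic.simulate_beats(sch, pv, params, run_length_s=60.0, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.beat_times, y.beat_times)

    def test_run_too_short_raises(self):
        sch = synthetic.make_schedule(4, 2, seed=1)
        with pytest.raises(ValueError, match="cover"):
            synthetic.simulate_beats(sch, {t.stimulus_id: 5.0 for t in sch.trials},
                                     SubjectParams(), run_length_s=5.0, seed=0)

    def test_rate_driven_non_positive_reports_time(self):
        sch = synthetic.make_schedule(1, 1, 2.0, (4.0, 4.0), seed=0)
        params = SubjectParams(baseline_ibi=1.0, ibi_noise_sd=0.0, decel_gain_neg=20.0)
        with pytest.raises(ValueError, match="non-positive at t="):
            synthetic.simulate_beats(sch, {0: 1.0}, params, run_length_s=20.0, seed=0,
                                     start_time=-5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_and_physiological_for_default_config(self, seed):
        sch = synthetic.make_schedule(6, 2, seed=seed)
        pv = {t.stimulus_id: float(1 + (t.stimulus_id % 9)) for t in sch.trials}
        series = synthetic.simulate_beats(sch, pv, SubjectParams(), run_length_s=60.0,
                                          seed=seed, start_time=-5.0)
        for s in series:
            d = np.diff(s.beat_times)
            assert np.all(d > 0)
            assert np.all((d >= 0.3) & (d <= 2.0))

    def test_deceleration_depth_recovered_for_isolated_stimulus(self):
        # injected peak depth 8 bpm at perceived valence 1, gain 2 bpm/unit;
        # isolated stimulus so no preceding-trial contamination of baseline
        from scipy.integrate import quad

        sch = synthetic.make_schedule(1, 1, 2.0, (4.0, 4.0), seed=0)
        params = SubjectParams(baseline_ibi=0.85, ibi_noise_sd=0.02, decel_gain_neg=2.0)
        vals = []
        for rep in range(60):
            [beats] = synthetic.simulate_beats(sch, {0: 1.0}, params, run_length_s=30.0,
                                               seed=rep, start_time=-10.0)
            tc = hr.hr_change_timecourse(beats.beat_times, 0.0)
            vals.append(tc.bins[4])  # bin [2.0, 2.5) around the 2 s kernel peak
        factor = quad(lambda t: synthetic.deceleration_kernel(np.array([t]), 2.0)[0], 2.0, 2.5)[0] / 0.5
        assert np.mean(vals) == pytest.approx(-8.0 * factor, abs=1.0)


class TestActivations:
    def _scores(self, n=20, seed=0):
        return synthetic.sample_normative_scores(n, seed=seed)

    def test_noiseless_construction_is_rank_one(self):
        scores = self._scores()
        params = SubjectParams(activation_noise_sd=0.0, encoding_idiosyncrasy_sd=0.0)
        pv = {s.stimulus_id: s.valence for s in scores}
        pat = synthetic.simulate_activations(scores, pv, params, n_features=15, seed=1)
        assert np.linalg.matrix_rank(pat.matrix, tol=1e-10) == 1
        sig = np.array([pv[i] - 5.0 for i in pat.stimulus_ids])
        w = synthetic.cohort_shared_direction(15, 0)
        np.testing.assert_allclose(pat.matrix, np.outer(sig, w), atol=1e-12)

    def test_midpoint_stimulus_is_pure_noise(self):
        from affecthr.types import NormativeScore

        scores = [NormativeScore(0, 5.0, 5.0), NormativeScore(1, 2.0, 5.0)]
        params = SubjectParams(activation_noise_sd=0.0)
        pat = synthetic.simulate_activations(scores, {0: 5.0, 1: 2.0}, params, 10, seed=2)
        np.testing.assert_allclose(pat.matrix[0], np.zeros(10), atol=1e-12)

    def test_too_few_features_raises(self):
        with pytest.raises(ValueError):
            synthetic.simulate_activations(self._scores(), {}, SubjectParams(), 1, seed=0)


class TestBold:
    def test_single_stimulus_proportional_to_hrf(self):
        from affecthr.types import ActivationPatterns, StimulusSchedule, Trial

        sch = StimulusSchedule([Trial(0, 0, 0.0, 2.0)], n_runs=1)
        pat = ActivationPatterns(0, np.array([[2.0, -1.0]]), [0])
        [bold] = synthetic.simulate_bold(pat, sch, tr=1.0, noise_sd=0.0, seed=0)
        # columns proportional to each other with the pattern's ratio
        ratio = bold.matrix[:, 0] / np.where(bold.matrix[:, 1] != 0, bold.matrix[:, 1], np.nan)
        assert np.nanmax(np.abs(ratio + 2.0)) < 1e-9
        peak_t = np.argmax(np.abs(bold.matrix[:, 0]))
        assert 4 <= peak_t <= 8  # double-gamma peak near 6 s

    def test_linearity_of_forward_model(self):
        from affecthr.types import ActivationPatterns, StimulusSchedule, Trial

        sch = StimulusSchedule([Trial(0, 0, 0.0, 2.0), Trial(1, 0, 8.0, 2.0)], n_runs=1)
        p1 = ActivationPatterns(0, np.array([[1.0, 0.5], [0.3, -0.2]]), [0, 1])
        p2 = ActivationPatterns(0, np.array([[2.0, 1.0], [0.6, -0.4]]), [0, 1])
        [b1] = synthetic.simulate_bold(p1, sch, tr=2.0, noise_sd=0.0)
        [b2] = synthetic.simulate_bold(p2, sch, tr=2.0, noise_sd=0.0)
        np.testing.assert_allclose(b2.matrix, 2.0 * b1.matrix, atol=1e-12)

    def test_id_mismatch_raises(self):
        from affecthr.types import ActivationPatterns, StimulusSchedule, Trial

        sch = StimulusSchedule([Trial(0, 0, 0.0, 2.0)], n_runs=1)
        pat = ActivationPatterns(0, np.array([[1.0, 1.0]]), [99])
        with pytest.raises(ValueError, match="mismatch"):
            synthetic.simulate_bold(pat, sch, tr=2.0)


def test_hrf_unit_peak_and_undershoot():
    t = np.linspace(0, 32, 3201)
    h = double_gamma(t)
    assert h.max() == pytest.approx(1.0, abs=1e-6)
    assert t[np.argmax(h)] == pytest.approx(5.0, abs=1.5)  # peak near shape-1
    assert h[t > 12].min() < 0  # undershoot present
    assert double_gamma(np.array([-1.0]))[0] == 0.0
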