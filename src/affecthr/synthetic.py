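"""Synthetic cohort generator for the affective-valence induction study.

Emulates the acquisition the analysis assumes, with no downloads: 90 image
stimuli spanning the Likert valence axis 1-9, presented for 2 s with
inter-trial intervals uniform on 2-6 s, balanced over two runs; per-subject
heart-beat time series whose stimulus-locked deceleration depth scales with
the (perceived) negativity of the stimulus; per-stimulus activation patterns
with a linear valence encoding shared across the cohort plus a
subject-idiosyncratic component; and optionally BOLD-like feature series
obtained by pushing the patterns through a hemodynamic forward model.

The subject-idiosyncrasy machinery implements a simple theory of individual
differences: a subject's *perceived* valence diverges from the normative
score mostly for neutral stimuli (the divergence s.d. shrinks linearly to
zero at the Likert poles), and both the cardiac and the neural channel are
driven by perceived -- not normative -- valence. Every operation is a pure
function of its config and seed.
"""

from __future__ import annotations

import numpy as np

from .hrf import boxcar_hrf_regressor
from .types import (
    LIKERT_MAX,
    LIKERT_MIN,
    VALENCE_MID,
    ActivationPatterns,
    BeatSeries,
    BOLDSeries,
    NormativeScore,
    StimulusSchedule,
    SubjectParams,
    Trial,
    valence_map,
)

DEFAULT_RUN_LENGTH_S = 555.0  # 9.25 min per run

__all__ = [
    "make_schedule",
    "sample_normative_scores",
    "perceived_valence",
    "deceleration_kernel",
    "simulate_beats",
    "simulate_activations",
    "simulate_bold",
    "DEFAULT_RUN_LENGTH_S",
]


def make_schedule(
    n_stim: int,
    n_runs: int,
    presentation_s: float = 2.0,
    iti_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
) -> StimulusSchedule:
    """Build a timed trial list with stimuli split equally across runs.

    Stimulus ids 0..n_stim-1 are assigned to runs round-robin (id j goes to
    run j mod n_runs).  Because :func:`sample_normative_scores` issues ids in
    valence order, this balances per-run mean valence.  Presentation order
    within each run is a seeded shuffle; gaps between trials are i.i.d.
    uniform on ``iti_range``.
    """
    if n_stim % n_runs != 0:
        raise ValueError(f"n_stim={n_stim} not divisible by n_runs={n_runs}")
    if presentation_s <= 0:
        raise ValueError("presentation_s must be positive")
    lo, hi = iti_range
    if lo > hi or lo < 0:
        raise ValueError(f"invalid iti_range {iti_range}")

    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for run in range(n_runs):
        ids = np.arange(run, n_stim, n_runs)
        rng.shuffle(ids)
        onset = 0.0
        for j, sid in enumerate(ids):
            trials.append(Trial(int(sid), run, onset, presentation_s))
            if j < len(ids) - 1:
                onset += presentation_s + rng.uniform(lo, hi)
    return StimulusSchedule(trials, n_runs, presentation_s, iti_range)


def sample_normative_scores(
    n_stim: int, seed: int = 0, arousal_envelope: bool = True
) -> list[NormativeScore]:
    """Stratified synthetic normative scores spanning the valence axis.

    One uniform valence draw per stratum of an n_stim-fold partition of
    [1, 9], so every unit-width valence band is populated for n_stim >= 16.
    Arousal is drawn inside a V-shaped valence-conditional band (neutral
    stimuli calm, polar-extreme stimuli arousing), mimicking the empirical
    shape of normative affect ratings; set ``arousal_envelope=False`` for
    unconditional uniform arousal.  Stimulus ids are issued in valence order.
    """
    if n_stim < 2:
        raise ValueError("need at least 2 stimuli")
    rng = np.random.default_rng(seed)
    edges = np.linspace(LIKERT_MIN, LIKERT_MAX, n_stim + 1)
    valences = rng.uniform(edges[:-1], edges[1:])
    scores = []
    for sid, v in enumerate(np.sort(valences)):
        if arousal_envelope:
            lo = LIKERT_MIN + 0.8 * abs(v - VALENCE_MID)
            hi = min(LIKERT_MAX, lo + 3.5)
            arousal = rng.uniform(lo, hi)
        else:
            arousal = rng.uniform(LIKERT_MIN, LIKERT_MAX)
        scores.append(NormativeScore(sid, float(v), float(arousal)))
    return scores


def perceived_valence(
    scores: list[NormativeScore], params: SubjectParams, seed: int = 0
) -> dict[int, float]:
    """Subject-specific perceived valence per stimulus.

    perceived_j = clip(v_j + eta_j, 1, 9) with eta_j ~ N(0, sd_j) and
    sd_j = sd0 * max(0, 1 - |v_j - 5| / 4): full divergence at the neutral
    midpoint, none at the Likert poles.  Clipping is truncation, not
    resampling.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for s in scores:
        sd = params.perceived_divergence_sd0 * max(0.0, 1.0 - abs(s.valence - VALENCE_MID) / 4.0)
        eta = rng.normal(0.0, sd) if sd > 0 else 0.0
        out[s.stimulus_id] = float(np.clip(s.valence + eta, LIKERT_MIN, LIKERT_MAX))
    return out


_KERNEL_SHAPE = 3.0  # gamma shape of the deceleration bump


def deceleration_kernel(t: np.ndarray, peak_time: float) -> np.ndarray:
    """Unit-peak gamma-density bump peaking at ``peak_time`` s post-onset.

    Closed form of the shape-k gamma density normalised to unit peak:
    K(t) = (t/p)^(k-1) * exp((k-1) * (1 - t/p)), evaluated directly (this
    sits in the per-beat inner loop of the beat simulator).
    """
    t = np.asarray(t, dtype=float)
    km1 = _KERNEL_SHAPE - 1.0
    with np.errstate(invalid="ignore"):
        ratio = np.where(t > 0, t / peak_time, 0.0)
        k = ratio**km1 * np.exp(km1 * (1.0 - ratio))
    return np.where(t <= 0, 0.0, k)


def _triphasic_kernel(t: np.ndarray, peak_time: float) -> np.ndarray:
    """Decelerate-accelerate-decelerate shape for positive stimuli, unit
    initial-deceleration peak."""
    return (
        deceleration_kernel(t, peak_time)
        - 0.8 * deceleration_kernel(t, peak_time + 2.0)
        + 0.5 * deceleration_kernel(t, peak_time + 4.0)
    )


def instantaneous_rate(
    t: np.ndarray,
    schedule_onsets: np.ndarray,
    depths_neg: np.ndarray,
    depths_pos: np.ndarray,
    params: SubjectParams,
) -> np.ndarray:
    """bpm(t) = 60/baseline_ibi minus the summed stimulus-locked kernels."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    onsets = np.asarray(schedule_onsets, dtype=float)
    rate = np.full(t.shape, 60.0 / params.baseline_ibi)
    rel = t[:, None] - onsets[None, :]  # times x onsets
    if np.any(depths_neg > 0):
        rate -= deceleration_kernel(rel, params.kernel_peak_time) @ depths_neg
    if np.any(depths_pos > 0):
        rate -= _triphasic_kernel(rel, params.kernel_peak_time) @ depths_pos
    return rate


def simulate_beats(
    schedule: StimulusSchedule,
    perceived: dict[int, float],
    params: SubjectParams,
    run_length_s: float = DEFAULT_RUN_LENGTH_S,
    seed: int = 0,
    start_time: float = 0.0,
) -> list[BeatSeries]:
    """Generate beat-time series per run from an instantaneous-rate model.

    The heart rate dips below its baseline after each stimulus by a
    gamma-shaped deceleration bump whose depth is decel_gain_neg * (5 -
    perceived) for negative stimuli (and, when ``triphasic`` is set, a
    triphasic shape scaled by decel_gain_pos * (perceived - 5) for positive
    ones).  Beats are emitted by stepping the rate model: next beat =
    previous + 60/bpm(previous) + Gaussian IBI jitter.  ``start_time`` may be
    negative to provide a pre-first-stimulus lead-in for baseline estimation.
    """
    last_end = max(t.onset + t.duration for t in schedule.trials)
    if run_length_s < last_end + 6.0:
        raise ValueError(
            f"run_length_s={run_length_s} does not cover trials + 6 s (need {last_end + 6.0})"
        )
    rng = np.random.default_rng(seed)
    series = []
    for run in range(schedule.n_runs):
        trials = schedule.run_trials(run)
        onsets = np.array([t.onset for t in trials])
        pv = np.array([perceived[t.stimulus_id] for t in trials])
        depths_neg = params.decel_gain_neg * np.maximum(0.0, VALENCE_MID - pv)
        depths_pos = (
            params.decel_gain_pos * np.maximum(0.0, pv - VALENCE_MID)
            if params.triphasic
            else np.zeros_like(pv)
        )
        beats = []
        t = start_time
        while t < run_length_s:
            beats.append(t)
            bpm = float(instantaneous_rate(t, onsets, depths_neg, depths_pos, params)[0])
            if bpm <= 0:
                raise ValueError(f"rate model non-positive at t={t:.3f} s (run {run})")
            ibi = 60.0 / bpm
            # a long interval can step over a deep dip; scan it for a
            # non-positive instantaneous rate
            if ibi > 0.25 and (np.any(depths_neg > 0) or np.any(depths_pos > 0)):
                grid = t + np.arange(0.25, ibi, 0.25)
                if grid.size:
                    rates = instantaneous_rate(grid, onsets, depths_neg, depths_pos, params)
                    if np.any(rates <= 0):
                        bad = float(grid[int(np.argmax(rates <= 0))])
                        raise ValueError(f"rate model non-positive at t={bad:.3f} s (run {run})")
            if params.ibi_noise_sd > 0:
                ibi += rng.normal(0.0, params.ibi_noise_sd)
            if ibi <= 0:
                raise ValueError(f"IBI jitter produced non-positive interval at t={t:.3f} s")
            t += ibi
        series.append(BeatSeries(params.subject_id, run, np.array(beats)))
    return series


def simulate_activations(
    scores: list[NormativeScore],
    perceived: dict[int, float],
    params: SubjectParams,
    n_features: int,
    seed: int = 0,
    cohort_seed: int = 0,
) -> ActivationPatterns:
    """Per-stimulus activation patterns with a linear valence encoding.

    pattern_j = (w_shared * encoding_shared_weight
                 + w_subj * encoding_idiosyncrasy_sd) * (perceived_j - 5)
                + eps_j,  eps ~ N(0, activation_noise_sd) elementwise.

    ``w_shared`` is a unit-norm direction drawn from ``cohort_seed`` (fixed
    across subjects); ``w_subj`` is a subject-specific unit-norm direction
    drawn from ``seed``.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    cohort_rng = np.random.default_rng(cohort_seed)
    w_shared = cohort_rng.normal(size=n_features)
    w_shared /= np.linalg.norm(w_shared)
    rng = np.random.default_rng(seed)
    w_subj = rng.normal(size=n_features)
    w_subj /= np.linalg.norm(w_subj)

    direction = params.encoding_shared_weight * w_shared + params.encoding_idiosyncrasy_sd * w_subj
    ids = [s.stimulus_id for s in scores]
    signal = np.array([perceived[i] - VALENCE_MID for i in ids])
    matrix = np.outer(signal, direction)
    if params.activation_noise_sd > 0:
        matrix = matrix + rng.normal(0.0, params.activation_noise_sd, size=matrix.shape)
    return ActivationPatterns(params.subject_id, matrix, ids)


def cohort_shared_direction(n_features: int, cohort_seed: int = 0) -> np.ndarray:
    """The unit-norm shared encoding direction for a given cohort seed."""
    rng = np.random.default_rng(cohort_seed)
    w = rng.normal(size=n_features)
    return w / np.linalg.norm(w)


def simulate_bold(
    patterns: ActivationPatterns,
    schedule: StimulusSchedule,
    tr: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_vols_per_run: int | None = None,
) -> list[BOLDSeries]:
    """Hemodynamic forward model: patterns -> BOLD-like feature series.

    Each feature's series is the sum over that run's trials of the stimulus
    boxcar convolved with the canonical double-gamma HRF, scaled by the
    stimulus's pattern value, sampled at ``tr``, plus white Gaussian noise.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    sched_ids = set(schedule.stimulus_ids)
    pat_ids = set(patterns.stimulus_ids)
    if sched_ids != pat_ids:
        raise ValueError(
            f"schedule/pattern stimulus-id mismatch: only-in-schedule={sorted(sched_ids - pat_ids)[:5]}, "
            f"only-in-patterns={sorted(pat_ids - sched_ids)[:5]}"
        )
    row_of = {sid: k for k, sid in enumerate(patterns.stimulus_ids)}
    rng = np.random.default_rng(seed)
    out = []
    for run in range(schedule.n_runs):
        trials = schedule.run_trials(run)
        last_end = max(t.onset + t.duration for t in trials)
        n_vols = n_vols_per_run or int(np.ceil((last_end + 16.0) / tr))
        vol_times = np.arange(n_vols) * tr
        matrix = np.zeros((n_vols, patterns.matrix.shape[1]))
        for trial in trials:
            reg = boxcar_hrf_regressor(vol_times, trial.onset, trial.duration)
            matrix += np.outer(reg, patterns.matrix[row_of[trial.stimulus_id]])
        if noise_sd > 0:
            matrix += rng.normal(0.0, noise_sd, size=matrix.shape)
        out.append(BOLDSeries(patterns.subject_id, run, matrix, tr))
    return out
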