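"""Stimulus-locked heart-rate-change analysis from beat times.

Beat times (e.g. from photoplethysmography after beat detection) are
converted to inter-beat intervals (IBIs), each assigned to the time of the
second beat of its pair.  For each trial, heart rate over eight half-second
bins spanning 0-4 s post-onset is estimated by time-fractionally weighting
every IBI whose span overlaps the bin, converted to bpm (60/IBI), and
referenced to a baseline computed from IBIs whose second beat falls within
one second before onset.  The cohort-level time of peak deceleration,
tps_max, is the minimum of the group-mean trajectory averaged over
negatively valent stimuli (normative valence < 5); the scalar cardiac
measure dHR for each trial is the value of the bin containing tps_max.

Conventions (the field's papers rarely state them): an IBI with second-beat
time t and length d occupies the span (t - d, t]; bins are half-open
[a, b); post-stimulus beats are those in (onset, onset + 4]; baseline beats
are those in [onset - 1, onset), their predecessor beat may be earlier.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    BIN_WIDTH,
    N_BINS,
    POST_WINDOW,
    PRE_WINDOW,
    VALENCE_MID,
    BeatSeries,
    GroupTimecourse,
    HRChangeTimecourse,
    IBISeries,
    NormativeScore,
    StimulusSchedule,
)

logger = logging.getLogger(__name__)

__all__ = [
    "beats_to_ibis",
    "pre_stimulus_baseline",
    "hr_change_timecourse",
    "timecourses_for_subject",
    "group_mean_timecourses",
    "find_tps_max",
    "delta_hr",
    "tps_max_bin_index",
]


def beats_to_ibis(beat_times: np.ndarray, window: tuple[float, float]) -> IBISeries:
    """IBIs for every beat inside ``window`` = (a, b] (second beat of pair).

    The predecessor beat may lie outside the window ("beats falling outside
    the strict time intervals" are used to form a pair); a beat with no
    predecessor yields no IBI.  An empty result is returned, not raised.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    a, b = window
    times, intervals = [], []
    for i in range(1, len(beat_times)):
        t = beat_times[i]
        if a < t <= b:
            times.append(t)
            intervals.append(t - beat_times[i - 1])
    return IBISeries(np.array(times), np.array(intervals))


def pre_stimulus_baseline(beat_times: np.ndarray, onset: float) -> float | None:
    """Baseline bpm = 60 / mean(pre-stimulus IBIs), or None if none formable.

    Pre-stimulus beats are those in [onset - 1, onset); each contributes the
    IBI to its predecessor beat (which may be earlier than onset - 1).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    ibis = []
    for i in range(1, len(beat_times)):
        t = beat_times[i]
        if onset - PRE_WINDOW <= t < onset:
            ibis.append(t - beat_times[i - 1])
    if not ibis:
        return None
    return 60.0 / float(np.mean(ibis))


def _bin_edges(onset: float) -> np.ndarray:
    return onset + BIN_WIDTH * np.arange(N_BINS + 1)


def hr_change_timecourse(
    beat_times: np.ndarray,
    onset: float,
    stimulus_id: int = -1,
    subject_id: int = -1,
) -> HRChangeTimecourse:
    """Eight half-second bins of bpm change vs the pre-stimulus baseline.

    Within bin [a, b), each post-stimulus IBI (second-beat time t, length d,
    span (t - d, t]) contributes with weight equal to its overlap with the
    bin; the bin's weighted-mean IBI is converted to bpm and the baseline is
    subtracted.  A bin no IBI span overlaps is marked invalid; a missing
    baseline invalidates the whole trial.
    """
    baseline = pre_stimulus_baseline(beat_times, onset)
    bins = np.full(N_BINS, np.nan)
    valid = np.zeros(N_BINS, dtype=bool)
    if baseline is None:
        return HRChangeTimecourse(stimulus_id, subject_id, None, bins, valid)

    ibis = beats_to_ibis(beat_times, (onset, onset + POST_WINDOW))
    edges = _bin_edges(onset)
    for k in range(N_BINS):
        lo, hi = edges[k], edges[k + 1]
        wsum = 0.0
        wxsum = 0.0
        for t, d in zip(ibis.times, ibis.intervals):
            overlap = min(t, hi) - max(t - d, lo)
            if overlap > 0:
                wsum += overlap
                wxsum += overlap * d
        if wsum > 0:
            weighted_ibi = wxsum / wsum
            bins[k] = 60.0 / weighted_ibi - baseline
            valid[k] = True
    return HRChangeTimecourse(stimulus_id, subject_id, baseline, bins, valid)


def timecourses_for_subject(
    beats: list[BeatSeries], schedule: StimulusSchedule
) -> list[HRChangeTimecourse]:
    """HR-change time course for every trial of one subject."""
    by_run = {b.run: b for b in beats}
    out = []
    for trial in schedule.trials:
        series = by_run[trial.run]
        out.append(
            hr_change_timecourse(
                series.beat_times, trial.onset, trial.stimulus_id, series.subject_id
            )
        )
    return out


def group_mean_timecourses(timecourses: list[HRChangeTimecourse]) -> list[GroupTimecourse]:
    """Per-stimulus, per-bin mean over subjects with that bin valid."""
    by_stim: dict[int, list[HRChangeTimecourse]] = {}
    for tc in timecourses:
        by_stim.setdefault(tc.stimulus_id, []).append(tc)
    out = []
    for sid in sorted(by_stim):
        tcs = by_stim[sid]
        mean_bins = np.full(N_BINS, np.nan)
        n_contrib = np.zeros(N_BINS, dtype=int)
        for k in range(N_BINS):
            vals = [tc.bins[k] for tc in tcs if tc.bin_valid[k]]
            if vals:
                mean_bins[k] = float(np.mean(vals))
                n_contrib[k] = len(vals)
        if n_contrib.sum() == 0:
            logger.warning("stimulus %d has no valid timecourse bins; excluded", sid)
            continue
        out.append(GroupTimecourse(sid, mean_bins, n_contrib))
    return out


def find_tps_max(group: list[GroupTimecourse], scores: list[NormativeScore]) -> float:
    """Cohort-level time of peak deceleration (seconds post-onset).

    Average the group-mean trajectories over negatively valent stimuli
    (normative valence < 5); tps_max is the midpoint of the bin holding the
    minimum, ties broken earliest.
    """
    val = {s.stimulus_id: s.valence for s in scores}
    neg = [g for g in group if val.get(g.stimulus_id, VALENCE_MID) < VALENCE_MID]
    if not neg:
        raise ValueError("no negatively valent stimuli (valence < 5) in group timecourses")
    with np.errstate(invalid="ignore"):
        traj = np.nanmean(np.stack([g.mean_bins for g in neg]), axis=0)
    if np.all(np.isnan(traj)):
        raise ValueError("negative-stimulus trajectory has no valid bins")
    k = int(np.nanargmin(traj))  # nanargmin returns the earliest minimum
    return (k + 0.5) * BIN_WIDTH


def tps_max_bin_index(tps_max: float) -> int:
    if not (0.0 < tps_max <= POST_WINDOW):
        raise ValueError(f"tps_max={tps_max} outside (0, {POST_WINDOW}]")
    return min(int(tps_max / BIN_WIDTH), N_BINS - 1)


def delta_hr(timecourse: HRChangeTimecourse, tps_max: float) -> float | None:
    """HR change (bpm) at tps_max, or None if the trial cannot contribute."""
    k = tps_max_bin_index(tps_max)
    if timecourse.baseline_missing or not timecourse.bin_valid[k]:
        return None
    return float(timecourse.bins[k])
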