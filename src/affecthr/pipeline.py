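"""End-to-end orchestration: simulate -> HR -> (betas) -> MVPA -> GLMM -> sweep.

Each stage is a function over in-memory objects so tests and scripts can
call any slice of the pipeline; :func:`run_all` wires them together, writes
every intermediate under the run directory with fixed names, and closes
with a manifest of content hashes, so identical config + seed yields an
identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import betas as betas_mod
from . import glmm as glmm_mod
from . import hr as hr_mod
from . import io as io_mod
from . import mvpa as mvpa_mod
from . import sweep as sweep_mod
from . import synthetic
from .seeds import substream_seed
from .types import (
    ActivationPatterns,
    BeatSeries,
    HRChangeTimecourse,
    N_BINS,
    NormativeScore,
    StimulusSchedule,
)

logger = logging.getLogger(__name__)

BEAT_LEAD_IN_S = -5.0  # beats start 5 s before the first stimulus

__all__ = ["Cohort", "simulate_cohort", "hr_stage", "mvpa_stage", "merge_stage", "run_all"]


@dataclasses.dataclass
class Cohort:
    schedule: StimulusSchedule
    scores: list[NormativeScore]
    perceived: dict[int, dict[int, float]]  # subject -> stimulus -> perceived valence
    beats: dict[int, list[BeatSeries]]
    patterns: dict[int, ActivationPatterns]


def simulate_cohort(config: io_mod.RunConfig) -> Cohort:
    """Generate the full synthetic cohort from the master seed.

    Cohort-level streams (scores, schedule, shared encoding direction) and
    per-subject streams (perceived valence, beats, activations, BOLD noise)
    are all derived from the master seed by the documented sha256 rule.
    """
    master = config.seed
    scores = synthetic.sample_normative_scores(
        config.n_stim, seed=substream_seed(master, "cohort", "scores")
    )
    schedule = synthetic.make_schedule(
        config.n_stim,
        config.n_runs,
        config.presentation_s,
        config.iti_range,
        seed=substream_seed(master, "cohort", "schedule"),
    )
    w_shared_seed = substream_seed(master, "cohort", "w_shared")
    perceived, beats, patterns = {}, {}, {}
    for sid in range(config.n_subjects):
        params = config.subject(sid)
        pv = synthetic.perceived_valence(
            scores, params, seed=substream_seed(master, sid, "perceived")
        )
        perceived[sid] = pv
        beats[sid] = synthetic.simulate_beats(
            schedule,
            pv,
            params,
            run_length_s=config.run_length_s,
            seed=substream_seed(master, sid, "beats"),
            start_time=BEAT_LEAD_IN_S,
        )
        direct = synthetic.simulate_activations(
            scores,
            pv,
            params,
            config.n_features,
            seed=substream_seed(master, sid, "activations"),
            cohort_seed=w_shared_seed,
        )
        if config.use_beta_series:
            last_end = max(t.onset + t.duration for t in schedule.trials)
            n_vols = int(np.ceil((last_end + 16.0) / config.tr))
            bold = synthetic.simulate_bold(
                direct,
                schedule,
                tr=config.tr,
                noise_sd=config.bold_noise_sd,
                seed=substream_seed(master, sid, "bold"),
                n_vols_per_run=n_vols,
            )
            design = betas_mod.build_design_matrix(schedule, n_vols, config.tr)
            patterns[sid] = betas_mod.fit_betas(bold, design)
        else:
            patterns[sid] = direct
    return Cohort(schedule, scores, perceived, beats, patterns)


def hr_stage(
    cohort: Cohort,
) -> tuple[list[HRChangeTimecourse], list, float, list[tuple[int, int, float | None]]]:
    """Per-trial timecourses, group means, cohort tps_max, and dHR rows."""
    timecourses = []
    for sid, beat_series in cohort.beats.items():
        timecourses.extend(hr_mod.timecourses_for_subject(beat_series, cohort.schedule))
    group = hr_mod.group_mean_timecourses(timecourses)
    tps_max = hr_mod.find_tps_max(group, cohort.scores)
    dhr_rows = [
        (tc.subject_id, tc.stimulus_id, hr_mod.delta_hr(tc, tps_max)) for tc in timecourses
    ]
    n_drop = sum(1 for _, _, v in dhr_rows if v is None)
    logger.info("hr stage: %d trials, %d with missing dHR, tps_max=%.2f s",
                len(dhr_rows), n_drop, tps_max)
    return timecourses, group, tps_max, dhr_rows


def mvpa_stage(cohort: Cohort, hyperparams=None) -> dict[int, dict[int, float]]:
    """Per-subject LOOCV valence predictions."""
    predictions = {}
    for sid, patterns in cohort.patterns.items():
        pset = mvpa_mod.loocv_predict(patterns, cohort.scores, hyperparams)
        predictions[sid] = pset.predictions()
    return predictions


def merge_stage(
    dhr_rows: list[tuple[int, int, float | None]],
    predictions: dict[int, dict[int, float]],
    scores: list[NormativeScore],
) -> pd.DataFrame:
    valences = {s.stimulus_id: s.valence for s in scores}
    return glmm_mod.build_model_table(dhr_rows, predictions, valences)


def _timecourses_frame(timecourses: list[HRChangeTimecourse]) -> pd.DataFrame:
    rows = []
    for tc in timecourses:
        row = {
            "subject_id": tc.subject_id,
            "stimulus_id": tc.stimulus_id,
            "baseline_bpm": np.nan if tc.baseline_missing else tc.baseline_bpm,
        }
        for k in range(N_BINS):
            row[f"bin_{k}"] = tc.bins[k]
            row[f"valid_{k}"] = bool(tc.bin_valid[k])
        rows.append(row)
    return pd.DataFrame(rows)


def _group_frame(group) -> pd.DataFrame:
    rows = []
    for g in group:
        row = {"stimulus_id": g.stimulus_id}
        for k in range(N_BINS):
            row[f"mean_bin_{k}"] = g.mean_bins[k]
            row[f"n_{k}"] = int(g.n_contributing[k])
        rows.append(row)
    return pd.DataFrame(rows)


def _glmm_report(result: glmm_mod.GLMMResult) -> dict:
    return {
        "fixed": list(result.spec.fixed),
        "random": list(result.spec.random),
        "coefficients": {k: float(v) for k, v in result.params.items()},
        "se": {k: float(v) for k, v in result.bse.items()},
        "p": {k: float(v) for k, v in result.pvalues.items()},
        "log_likelihood": result.llf,
        "r2": result.r2,
        "n_obs": result.n_obs,
        "converged": result.converged,
        "singular": result.singular,
    }


def run_all(config: io_mod.RunConfig) -> dict:
    """Run every stage, write all intermediates and a hash manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")

    stage = "simulate"
    try:
        cohort = simulate_cohort(config)
        io_mod.write_events(cohort.schedule, cohort.scores, outdir)
        io_mod.write_scores(cohort.scores, outdir / "scores.tsv")
        for sid, beat_series in cohort.beats.items():
            io_mod.write_beats(beat_series, outdir / f"beats_sub{sid:03d}.csv")
        for sid, pat in cohort.patterns.items():
            io_mod.write_patterns(pat, outdir / f"patterns_sub{sid:03d}.tsv")

        stage = "hr"
        timecourses, group, tps_max, dhr_rows = hr_stage(cohort)
        _timecourses_frame(timecourses).to_csv(outdir / "timecourses.tsv", sep="\t", index=False)
        _group_frame(group).to_csv(outdir / "group_timecourses.tsv", sep="\t", index=False)
        (outdir / "group_timecourses.json").write_text(json.dumps({"tps_max_s": tps_max}))

        stage = "mvpa"
        predictions = mvpa_stage(cohort, config.hyperparams())
        pred_rows = []
        vmap = {s.stimulus_id: s.valence for s in cohort.scores}
        for sid, preds in predictions.items():
            for stim, yhat in preds.items():
                pred_rows.append(
                    {"subject_id": sid, "stimulus_id": stim, "y_norm": vmap[stim], "y_pred": yhat}
                )
        pd.DataFrame(pred_rows).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

        stage = "merge"
        table = merge_stage(dhr_rows, predictions, cohort.scores)
        table.to_csv(outdir / "model_table.tsv", sep="\t", index=False)

        stage = "glmm"
        combined = glmm_mod.fit_glmm(
            table.dropna(subset=["delta_hr", "svm_pred"]),
            glmm_mod.GLMMSpec("valence_norm", ("delta_hr", "svm_pred")),
        )
        effects = glmm_mod.effect_size_r2(
            table, ["delta_hr", "svm_pred"], mode="separate", use_random=config.use_random
        )
        uniqueness = glmm_mod.uniqueness_analysis(table, use_random=config.use_random)
        report = {
            "tps_max_s": tps_max,
            "combined": _glmm_report(combined),
            "effect_sizes": {
                m: {"r2": e.r2, "p_fixed": e.p_fixed, "beta": e.beta, "used_random": e.used_random}
                for m, e in effects.items()
            },
            "uniqueness": {name: _glmm_report(res) for name, res in uniqueness.items()},
        }
        (outdir / "glmm_report.json").write_text(json.dumps(report, indent=2))

        stage = "sweep"
        sweep_rows = sweep_mod.sweep(
            table, cohort.scores, config.thresholds, use_random=config.use_random
        )
        sweep_mod.sweep_frame(sweep_rows).to_csv(outdir / "sweep.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {}
    for path in sorted(outdir.iterdir()):
        # the resolved config embeds the output path itself, so hashing it
        # would make manifests differ across otherwise identical runs
        if path.name in ("manifest.json", "config_resolved.yaml") or path.is_dir():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run_all finished in %.1f s (%d files)", time.time() - t0, len(manifest))
    return {
        "table": table,
        "tps_max": tps_max,
        "report": report,
        "sweep": sweep_rows,
        "manifest": manifest,
    }
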