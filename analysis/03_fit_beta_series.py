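#!/usr/bin/env python
"""Demonstrate the beta-series stage: BOLD-like series -> activation patterns.

For a handful of subjects, pushes the generated activation patterns through
the hemodynamic forward model (one double-gamma-convolved boxcar per
stimulus), adds white noise, refits the beta-series GLM, and reports how
well the single-trial betas recover the generating patterns.  On real data
this stage replaces the directly generated patterns; downstream decoding is
agnostic to which route produced them.
"""

import argparse
from pathlib import Path

import numpy as np

from affecthr import betas, io, synthetic


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run-dir", type=Path, default=Path("results/run"))
    ap.add_argument("--subjects", type=int, default=3)
    ap.add_argument("--noise-sd", type=float, default=0.5)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    schedule, _ = io.read_events(sorted(args.run_dir.glob("events_run*.tsv")))
    last_end = max(t.onset + t.duration for t in schedule.trials)
    n_vols = int(np.ceil((last_end + 16.0) / 2.0))
    design = betas.build_design_matrix(schedule, n_vols, tr=2.0)
    print(f"design: {design.matrix.shape[0]} volumes x {design.matrix.shape[1]} regressors "
          f"({design.n_stimuli} stimulus + drift)")

    for sid in range(args.subjects):
        pat = io.read_patterns(args.run_dir / f"patterns_sub{sid:03d}.tsv", subject_id=sid)
        for label, noise in (("noiseless", 0.0), ("noisy", args.noise_sd)):
            bold = synthetic.simulate_bold(pat, schedule, tr=2.0, noise_sd=noise,
                                           seed=args.seed + sid, n_vols_per_run=n_vols)
            rec = betas.fit_betas(bold, design)
            idx = np.argsort(pat.stimulus_ids)
            err = np.max(np.abs(rec.matrix - pat.matrix[idx]))
            corr = np.corrcoef(rec.matrix.ravel(), pat.matrix[idx].ravel())[0, 1]
            print(f"  subject {sid} ({label}, sd={noise}): "
                  f"max |beta error| = {err:.2e}, pattern correlation = {corr:.4f}")
        io.write_patterns(rec, args.run_dir / f"patterns_glm_sub{sid:03d}.tsv")
    print("noiseless recovery is exact to solver precision; "
          "noisy recovery degrades gracefully with the GLM leverage")


if __name__ == "__main__":
    main()
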