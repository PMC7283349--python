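# affecthr

Combined cardiac and neural-pattern measurement of affective valence
induction, as a tested, reusable analysis pipeline.

## The problem

When an emotionally evocative picture is shown, the heart transiently
decelerates — more deeply for unpleasant pictures — and distributed brain
activation patterns encode the picture's affective valence. This package
implements the full analysis chain needed to compare these two channels as
*measures* of valence induction on one stimulus set:

1. **Heart-rate change (ΔHR).** Beat times are converted to inter-beat
   intervals (IBI; heart rate in bpm = 60/IBI). For each trial, bpm change
   relative to a 1 s pre-stimulus baseline is computed over eight
   half-second bins spanning 0–4 s post-onset, each bin taking the
   time-fractionally-weighted mean of the IBIs overlapping it. The cohort
   time of peak deceleration, `tps_max`, is the minimum of the group-mean
   trajectory over negatively valent stimuli (normative valence < 5); ΔHR
   for every trial is the value of the bin containing `tps_max`.
2. **Multivoxel pattern decoding.** Per-stimulus activation patterns — a
   beta series: one GLM regressor per stimulus, its presentation boxcar
   convolved with the canonical double-gamma HRF — feed an intra-subject
   leave-one-out cross-validated linear support-vector regression
   (C = 1, ε = IQR(y)/13.49) that predicts each held-out stimulus's
   normative valence.
3. **Mixed-effects combination.** ΔHR and the out-of-fold SVR predictions
   enter a linear mixed model of normative valence with subject-wise random
   intercept/slopes (kept only when a likelihood-ratio test retains them;
   ML estimation). Per-channel effect size is residual-based
   R² = 1 − SS_res/SS_tot from a separate single-measure model.
4. **Polar-extremity sweep.** The analysis is repeated while excluding
   neutral stimuli (|valence − 5| < t) for t = 0…3 in steps of 0.2,
   reporting per-threshold R², class mean valences, and fraction of
   stimuli kept — because the published literature uses stimulus sets of
   wildly different polar-extremity.

Real acquisitions of this kind (fMRI + photoplethysmography with licensed
normative picture sets) cannot be redistributed, so the package ships a
**synthetic cohort generator** that emulates the design — 90 stimuli
spanning valence 1–9, 2 s presentations, 2–6 s ITIs over two 9.25-min
runs — with a known ground truth: stimulus-locked cardiac deceleration
scaled by perceived negativity, and a linear valence encoding in the
activation patterns plus subject idiosyncrasy concentrated on neutral
stimuli. Every downstream stage is testable against that ground truth.
See `docs/methods.md` for the models and all conventions.

## Worked example

The analysis is a sequence of numbered drivers (each is `--help`-documented
and writes its tables under `results/run/`):

```sh
python analysis/01_simulate_cohort.py --seed 1 --subjects 12
python analysis/02_hr_timecourses.py
python analysis/03_fit_beta_series.py
python analysis/04_decode_valence.py
python analysis/05_mixed_effects.py
python analysis/06_threshold_sweep.py
```

which prints, for seed 1 with 12 subjects (abridged):

```
cohort: 12 subjects, 90 stimuli over 2 runs
  valence span: 1.01-8.91
  total beats simulated: 15749
1080 trial timecourses from 12 subjects (0 with missing baseline)
  negative-stimulus group trajectory (bpm): [ 0.24 -0.08 -0.83 -1.29 -1.58 -1.6  -1.39 -1.2 ]
  positive-stimulus group trajectory (bpm): [0.25 0.34 0.37 0.37 0.5  0.6  0.61 0.68]
  tps_max = 2.75 s post-onset (deeper deceleration for negative stimuli)
design: 290 volumes x 96 regressors (90 stimulus + drift)
  subject 0 (noiseless, sd=0.0): max |beta error| = 1.71e-14, pattern correlation = 1.0000
decoded 12 subjects x 90 stimuli (LOOCV, linear SVR)
  within-subject prediction/normative correlation: mean 0.927, range 0.890-0.957
model table: 1080 rows (0 missing dHR)
  combined model R2 = 0.862
  delta_hr: separate R2 = 0.1907, beta = 0.3849, p = 1.66e-51, random effects kept: False
  svm_pred: separate R2 = 0.8587, beta = 1.0534, p = 0.00e+00, random effects kept: False
  uniqueness: dHR error predicts SVR error with p = 1.05e-32 (shared perceived-valence signal couples the channels)
sweep: 16 thresholds, 16 estimable
  SVR R2 exceeds dHR R2 at 100% of estimable thresholds
  fraction kept falls from 1.00 to 0.24 across the grid
```

Reading the numbers: the group-mean trajectory over negative stimuli dips
to its minimum near the generator's 2 s deceleration-kernel peak
(`tps_max` = 2.75 s here; the slight late drift on positive trials is the
documented baseline-contamination artifact of 2–6 s ITIs), the beta-series
GLM recovers noiseless patterns exactly, decoding recovers normative
valence within subjects at r ≈ 0.93, and with the generator's default
signal levels the neural channel explains more response variance than the
cardiac channel at every neutral-exclusion threshold, with the gap and the
R² both growing as neutral stimuli are excluded. On real data the absolute
R² values are far smaller — the synthetic cohort's white noise flatters
both channels — but the *structure* (channel ordering, R² growth with
polar-extremity) is the tested contract.

The same stages are also exposed as a CLI
(`affecthr simulate|hr|betas|mvpa|glmm|sweep|all`), e.g.

```sh
affecthr all --seed 1 --out results/cli_run
```

runs everything and writes a sha256 manifest; identical config + seed gives
byte-identical result tables.

## Layout

- `src/affecthr/` — library: `synthetic` (cohort generator), `hr`
  (IBI binning, tps_max, ΔHR), `betas` (beta-series GLM), `mvpa` (LOOCV
  SVR), `glmm` (mixed models, effect sizes, uniqueness), `sweep`
  (neutral-exclusion sweep), `io`/`pipeline`/`cli` (formats, orchestration,
  CLI).
- `analysis/` — numbered narrative drivers reproducing the analysis
  end-to-end on the synthetic cohort.
- `tests/` — unit, property and acceptance tests (including brute-force
  oracles for the binning arithmetic).
- `docs/methods.md` — models, parameter defaults with units and rationale,
  numerical conventions, known limitations.
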