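# Methods

`affecthr` implements a combined physiological + neural analysis of
affective-valence induction and a synthetic-data generator that emulates the
acquisition it assumes. This note records the models, the defaults and why,
the numerical choices, and what the synthetic cohort does and does not show
about real data.

## Study design emulated by the generator

Ninety image stimuli with normative 9-point Likert valence/arousal ratings
are presented for 2 s each, separated by inter-trial intervals drawn
uniformly from 2–6 s, balanced over two 555 s (9.25 min) runs. Normative
valence spans the full 1–9 axis approximately uniformly (one stratified
uniform draw per n-fold partition of the axis); arousal is drawn inside a
V-shaped valence-conditional band (neutral stimuli calm, polar-extreme
stimuli arousing), which mimics the empirical envelope of normative affect
ratings. The exact algorithm by which real stimulus sets are chosen to
"span" the affect plane is not standardised; stratified uniform sampling is
a stand-in, not a reconstruction of any licensed image set. Stimulus ids are
issued in valence order and assigned to runs round-robin, which balances
per-run mean valence.

### Individual differences (perceived valence)

Each subject's *perceived* valence of stimulus j is

    perceived_j = clip(v_j + eta_j, 1, 9),   eta_j ~ N(0, sd_j),
    sd_j = sd0 * max(0, 1 - |v_j - 5| / 4)

so disagreement with the normative score v_j is largest at the neutral
midpoint and vanishes at the Likert poles. Clipping is truncation, not
resampling. Both the cardiac and the neural channel are driven by perceived,
not normative, valence; this one latent variable is what couples the two
channels' prediction errors. Default sd0 = 1.0 Likert unit in the analysis
drivers (a visible but not dominant individual-difference signal); sd0 = 0
switches the mechanism off.

### Cardiac channel

Beats are emitted by integrating an instantaneous-rate model

    bpm(t) = 60 / baseline_ibi - sum_j depth_j * K(t - onset_j)

where K is a gamma-density bump (shape 3) normalised to unit peak at
`kernel_peak_time` (default 2.0 s post-onset, consistent with measuring
deceleration inside the 0–4 s window) and depth_j = decel_gain_neg *
max(0, 5 - perceived_j) bpm. An optional triphasic
(decelerate–accelerate–decelerate) shape scaled by decel_gain_pos applies to
positive stimuli; it is off by default because the modelled study observed
no positive-valence cardiac response. The next beat time is previous +
60/bpm(previous) + N(0, ibi_noise_sd) jitter. Defaults: baseline IBI 0.85 s
(~71 bpm), jitter 0.02 s, decel_gain_neg 1.0 bpm per Likert unit (peak 4 bpm
deceleration for the most negative stimuli — the few-bpm scale reported for
picture-viewing deceleration). Each run's beats start 5 s before the first
stimulus so that the first trial has a pre-stimulus baseline. The generator
deliberately reproduces one known artifact of dense designs: with 2–6 s
ITIs, the previous trial's deceleration can leak into the next trial's
1 s baseline window, slightly attenuating measured dHR. Recovery checks
therefore use isolated stimuli, where the injected kernel depth is recovered
to well within 1 bpm.

### Neural channel

Per-stimulus activation patterns over abstract features (columns, standing
in for grey-matter voxels; default 100–200 in the drivers):

    pattern_j = (w_shared * esw + w_subj * eis) * (perceived_j - 5) + eps_j

with w_shared a unit-norm direction fixed across the cohort (cohort-level
seed), w_subj a subject-specific unit-norm direction, and eps elementwise
N(0, activation_noise_sd). Defaults esw = 1, eis = 0.2, noise 0.5, which
puts single-subject LOOCV decoding correlations around 0.8–0.9 — an
optimistic but structurally faithful stand-in for beta-series decoding.
Optionally the patterns are pushed through a hemodynamic forward model
(each presentation boxcar convolved with the canonical double-gamma HRF,
sampled at tr = 2 s, plus white noise) and recovered by the beta-series GLM,
which is the route real data would take.

Spatial structure, smoothness, motion, drift beyond Legendre polynomials,
and physiological BOLD artifacts are *not* simulated; passing tests
demonstrate the statistical machinery, not robustness to real fMRI noise.

## Heart-rate-change pipeline

An IBI is the difference between successive beat times, assigned to the
second beat of the pair, and occupies the span (t − d, t]. Post-stimulus
IBIs are those whose second beat lies in (onset, onset + 4]; the baseline
uses IBIs whose second beat lies in [onset − 1, onset); in both cases the
predecessor beat may fall outside the window. The interval-end/bin-edge
conventions (half-open bins [a, b), span closed at its beat) are not
standardised in the field's reports; ours are fixed here and exercised
against a brute-force overlap-enumeration oracle.

Each of the eight half-second bins gets the time-fractionally-weighted mean
of the overlapping IBIs, converted to bpm (60/IBI), minus the baseline bpm.
A bin with no overlapping IBI span is invalid; a trial with no formable
pre-stimulus IBI has no baseline and is dropped listwise from the model
table (counts are logged — missing-data handling is otherwise unspecified in
the literature this follows).

tps_max is cohort-level: the group-mean trajectories of stimuli with
normative valence < 5 are averaged and the midpoint of the minimum bin is
taken, ties broken earliest. dHR for every trial is the value of the bin
containing tps_max (bin lookup, no interpolation); tps_max is computed once
on the full stimulus set and reused across sweep thresholds. Trials whose
tps_max bin is invalid are dropped. An optional IBI sanity filter (reject
intervals outside 0.3–2.0 s) exists but is off by default, since artifact
correction is upstream of this pipeline's inputs.

## Beta-series GLM

One design column per stimulus (unit boxcar over its presentation convolved
with the canonical double-gamma HRF: gamma shapes 6 and 16, rate 1,
undershoot ratio 1/6, unit peak normalisation), runs concatenated, per-run
Legendre drift polynomials up to order 2, optional user-supplied nuisance
columns (e.g. motion regressors loaded from file). Ordinary least squares
per feature; rank deficiency is detected and the offending columns named
via QR with column pivoting. The forward model and the design matrix share
one regressor implementation, so the noiseless round trip is exact to
solver precision (< 1e-6). Amplitude modulation of regressors and HRF
derivative terms are not modelled.

## LOOCV decoding

Linear epsilon-insensitive SVR, hyperparameters pinned to the reference
defaults of this estimator family: box constraint C = 1, epsilon =
IQR(y)/13.49, linear kernel, no feature standardisation (standardisation is
available but off; whether the original analyses standardised is not
recoverable). Solver tolerance 1e-6 with a deterministic exact solver. For
each subject, stimulus j is predicted by a model trained on the other M−1
pairs; the held-out id is recorded with each prediction, and the container
rejects any record whose fold bookkeeping disagrees (structural leakage
check). A per-subject feature-subset mask file stands in for grey-matter
masking. Encoding weights are summarised as the per-feature mean across
folds, optionally mapped through the activation-pattern (forward-model)
transform cov(X)·w̄, unit-normed.

## Mixed-effects modelling and effect sizes

Response: normative valence. Fixed effects: dHR and the out-of-fold SVR
prediction. Random effects: subject-wise intercept and slopes, estimated by
maximum likelihood (not REML) so nested models are likelihood-comparable.
Fixed-effect p-values are single-coefficient tests of beta = 0 (whether the
original "F-test" was a single-coefficient or model-comparison test is
ambiguous; with 1 numerator df they coincide). Random effects are kept only
when the likelihood-ratio test against the no-random-effects model is
significant at alpha = 0.05; the LRT reference is a plain chi-square on the
covariance-parameter-count difference, which is conservative at the
variance boundary (the 50:50 chi-square mixture is available as an option).
When the optimiser pins a variance component at exactly zero, the fit is
flagged singular and the boundary values (OLS likelihood, marginal
residuals) are substituted — these are the correct limits, not
approximations.

Effect size is residual-based, R² = 1 − SS_res/SS_tot, with residuals
conditional on the fitted random effects (the default residual of the
reference mixed-model implementations) and therefore equal to OLS residuals
whenever random effects are dropped. How per-measure R² should be
partitioned is genuinely open; the default is *separate* single-measure
models (each measure's R² from its own model), with semipartial
(R²_full − R²_without) available and recorded in output metadata.

### Uniqueness analyses and a caveat

Four models: (a) svm_pred ~ dHR; (b) SVR calibration error ~ valence;
(c) dHR calibration error ~ valence; (d) SVR error ~ dHR error. A channel's
"prediction" of valence is the fitted value of an OLS valence ~ channel
calibration; its error is response − fitted. Caveat: because both errors
contain the response's unexplained variance, they are intrinsically
positively coupled whenever the channels are imperfect measures
(cov ≈ (1−b)(1−c)·Var(valence) for calibration slopes' attenuation factors
b, c). Model (d) is therefore informative about *extra* coupling — e.g. a
shared latent perceived valence — only relative to that floor. The null
simulation in the tests uses high-fidelity channels with independent
channel noise, where the floor vanishes and the rejection rate calibrates
to alpha.

## Threshold sweep

Thresholds 0 to 3 in steps of 0.2 (16 rows). At threshold t, stimuli with
|valence − 5| < t are excluded (strict inequality, so endpoint stimuli at
exactly 5 ± t are kept); stimuli at exactly valence 5 are always excluded
because the midpoint partition cannot label them. Survivors are labelled
positive (> 5) or negative. Per threshold: separate-mode R² and
significance per measure, class mean/sd valences, fraction kept.
Thresholds leaving < 4 stimuli or a single class are emitted flagged
not-estimable rather than dropped, preserving the grid for plotting. With
valence uniform on [1, 9], the expected fraction kept at threshold t is
1 − t/4 — the "middle third" of the stimulus set is removed near t ≈ 1.3,
matching the field's intuition that the middle of the Likert range is
neutral.

## Determinism and problem sizes

Every stochastic stage derives its substream from the master seed as the
first 31 bits of sha256("master:subject:stream"), so cohorts are pure
functions of (config, seed), any subject can be regenerated in isolation,
and identical config + seed yields byte-identical output manifests
(sha256 per file; the resolved-config copy is excluded from the manifest
since it embeds the output path).

The test suite and the acceptance script run cohorts at reduced sizes
chosen to exercise every code path at meaningful statistical power while
keeping a full run in the minutes range: e.g. 20 subjects × 90 stimuli ×
100 features for the headline analysis, 15–20 cohorts for ordering checks,
200 replicates of 10 × 30 for null calibration, and 100 replicates of the
50 × 90 model-table recovery simulation (which bypasses signal generation
and tests the mixed-model stage directly). The analysis drivers default to
the full 50-subject cohort.

### LOOCV predictions are not null-calibrated

A subtlety worth flagging: under a global null (activation patterns carry
no valence signal), leave-one-out predictions are *not* independent of the
held-out labels. Removing stimulus j shifts the training-label mean to
(Σy − y_j)/(M − 1), so the prediction for j carries a systematic negative
dependence on y_j of order 1/(M − 1) — the familiar cross-validation
mean-shift artifact. Because the effect has the same sign for every
subject, it pools: a fixed-effect test of valence on the SVR predictions
over-rejects under the null (measured at roughly 15–35% instead of 5% for
10 subjects × 30 stimuli, growing with feature count as the decoder
interpolates the shifted training labels more tightly; at M = 90 the
per-subject bias is only ≈ −1/89 and permutation-null mean correlations
stay within ±0.05). The ΔHR fixed effect, which involves no
cross-validation, calibrates to alpha within binomial bounds. Any analysis
of this family that feeds out-of-fold predictions into a significance test
against the same labels inherits this artifact; null claims about the
decoder channel should rest on permutation tests of the correlation, not
on the fixed-effect p-value.

## Known limitations

- Abstract feature columns: no spatial structure, no anatomical masking
  beyond the feature-mask file, no 3-D volume handling.
- Beat detection, artifact correction and raw-waveform physiology are out
  of scope; beat times are trusted inputs.
- The generator's noise is white; real PPG and BOLD noise are structured
  (respiration, motion, drift), so absolute effect sizes here are not
  comparable to real-data values — only the *structure* of the results
  (channel ordering, growth with polar-extremity, null calibration) is.
- Gaussian mixed models only; no Satterthwaite/Kenward–Roger degrees of
  freedom; no multiple-testing correction across the uniqueness models.
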