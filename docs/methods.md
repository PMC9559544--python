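# Methods

This note documents the models, parameter choices and numerical decisions
behind `pupilbias`, and what the synthetic-data tests do and do not
establish about real recordings.

## The design being modelled

Two groups — smokers and non-smokers, 20 per group at the analysis stage —
complete a dot-probe task (DPT: 240 trials, 12 practice; two lateral
6° × 4.5° images with inner edges 2° from fixation; 1,500-ms SOA) and a
passive-viewing task (PV: 200 trials, 8 practice; 1-s scrambled-image
baseline, then 3 s of foveal image presentation; 30% of trials end with a
probe requiring speeded detection). Gaze and binocular pupil diameter are
sampled at 600 Hz. The quantity of interest is the NRS−control difference
in standardised pupil diameter: smokers tend toward relative *constriction*
to nicotine-related images and non-smokers toward relative *dilation*,
concentrated roughly 800–2,850 ms after image onset.

## Synthetic-data generator

The generator is the package's ground truth and operates at two tiers.

**Raw tier** (`generate_dataset`). Per participant and PV trial the latent
z-scale signal is a shared anticipatory dilation ramp plus autocorrelated
trial noise plus a participant-level condition offset:

* *Ramp*: saturating exponential `A(1 − e^(−t/τ))` with amplitude A = 1.0 z
  and τ = 1 s. Only the existence of a steep sustained dilation (driven by
  temporal expectation of the probe) is documented for this paradigm, so the
  shape is a modelling choice; both parameters are configurable.
* *Trial noise*: AR(1) at the 25-ms bin scale with φ = 0.95 and marginal
  SD 0.15 z, piecewise-constant across the 15 samples within a bin. The
  autocorrelation time (~0.5 s) mimics the slow dynamics of pupil noise.
* *Effect*: each participant draws an NRS−control offset δᵢ from their
  group's distribution — smokers N(−0.025, 0.075²), non-smokers
  N(+0.036, 0.067²), in z units — applied to NRS trials inside the
  800–2,850-ms window.

The latent signal is standardised against its own realised pooled binned
mean/SD *before* δᵢ is injected and the result mapped to millimetres
(participant base diameter ~4.6–4.7 mm, 0.35 mm per z unit), so the
pipeline's own per-participant z-transform returns the configured effect in
z units up to small filtering bias and measurement noise. Missingness is
then injected: blink gaps (Bernoulli onset at 0.1 events/s, geometric
length with 100-ms mean, both eyes invalidated), single-eye dropouts
(per-sample rate 0.005), and optional implausible diameters (<2 or >7 mm
with validity flags intact, as a tracker would emit them). DPT gaze paths
are rendered from a simulated fixation sequence (central fixation
200–400 ms, then alternating lateral fixations whose first side and
durations are calibrated to the groups' descriptive statistics: first
fixation lands on NRS with probability 0.50/0.49 for smokers/non-smokers;
dwell means 513/502 and 468/463 ms). RTs are lognormal with group- and
condition-specific means/SDs matching the published descriptives (e.g.
smokers' DPT 538 vs 547 ms for NRS- vs control-side targets).

**Bin tier** (`simulate_difference_curves`). For simulation studies
(permutation-test calibration, classifier recovery) the generator emits
participant-level NRS−control difference curves directly on the 25-ms
grid: δᵢ over the effect-window bins plus AR(1) residual noise (marginal
SD 0.03 z) pinned to 0 at the first bin, mirroring the realignment step.
Regenerating and preprocessing 600-Hz raw streams in these loops adds
runtime but no information, since the raw pipeline reduces each
participant to exactly such a curve; agreement of the two tiers is covered
by the raw-pipeline recovery and null tests.

**What the generator does not emulate**: pupillary light-reflex dynamics,
foreshortening error, smooth pursuit or microsaccades, luminance coupling
between image content and pupil, learning/fatigue across trials, and any
questionnaire-derived covariates. Passing tests therefore demonstrate that
the *analysis machinery* is correct and calibrated for data with the
assumed structure — not that the biological effect itself is reproduced.

## Preprocessing decisions

Stage order is fixed: binocular merge → plausibility filter → trial QC →
interpolation → low-pass → median binning → z-transform → realignment →
condition averaging. Within that:

* A sample is valid only when *both* eyes are valid; the merged value is
  their mean.
* Plausibility bounds 2–7 mm, exclusive (exactly 2.0 and 7.0 are kept).
* Trial rejection at missing fraction **> 0.40** (strict), computed over
  baseline+image samples after merge and plausibility filtering; the
  denominator choice (all samples of the trial) is ours.
* Participant rejection at valid-trial fraction **< 0.50** (strict),
  applied per task.
* Interior gaps are linearly interpolated; leading/trailing gaps take the
  nearest valid value (extension), a choice the source procedure leaves
  open.
* Low-pass: 3rd-order Butterworth at 4 Hz applied forward-backward
  (zero-phase, unit DC gain). The original filter parameters are not
  recoverable; 4 Hz preserves everything a 25-ms binned pupil signal can
  represent while suppressing residual high-frequency noise.
* Bins are half-open `[k·25, (k+1)·25)` ms, 0-based from image onset,
  negative indices for the baseline; each holds 15 samples at 600 Hz and
  takes their median.
* The z-transform pools the binned baseline+image values of all kept
  trials of a participant and uses the sample (n−1) SD; it is applied to
  PV data only. Pooling set and SD convention are our decisions.
* Realignment subtracts each trial's first image bin; interpolation
  precedes realignment, so a trial missing its first bin realigns on the
  interpolated value.

## Cluster-based permutation test

Pointwise statistic: Welch t with Welch–Satterthwaite df (two-sample) or
one-sample t (df = n−1). Cluster-forming threshold: the two-sided
pointwise α = 0.05 critical t at each bin's df, recomputed per permutation
because Welch df depends on the relabeling. Cluster statistic: mass (sum
of t), sign-homogeneous runs. Null: random group relabelings or
per-participant sign flips; the maximal |mass| per permutation.
p = (b+1)/(B+1) for Monte-Carlo draws, or the exact proportion over the
full enumeration (identity included) when the relabeling space is no
larger than the requested permutation count. The first bin of realigned
curves is identically 0 across participants; such constant-and-equal bins
carry t = 0 rather than raising an error, since they contain no group
information. The threshold, statistic and permutation scheme of the
original analysis are undocumented, so reported cluster bounds are
reproduced qualitatively on synthetic data, never asserted bit-exactly.

## Fixation detection and bias scores

Angular speed between consecutive samples is assigned to the trailing
sample, smoothed with a centered 3-sample moving average, and thresholded
at 30 deg/s (the published detector is parameter-adaptive; we fix the
threshold and expose it). Sub-threshold runs of ≥40 ms become fixations
with centroid = mean position. AOI membership is by centroid containment;
fixations straddling an edge count where their centroid falls. The first
fixation of a trial is the first *AOI-contained* fixation (central-cross
dwell is skipped). RT bias is control − NRS for both tasks, so positive
values index engagement with NRS; responses faster than 100 ms are
anticipations (exactly 100 ms is kept), practice trials are discarded, and
only correct responses enter RT means.

## Classification and inference

Logistic models are fitted by maximum likelihood (IRLS); perfect
separation or non-convergence triggers a ridge-penalised refit (λ = 10⁻⁴
on slopes, intercept unpenalised) and is flagged. Best-subset selection
fits all 2^k subsets (k ≤ 20 guard) and ranks by BIC
(deviance + ln(n)·(k+1)), ties to the smaller model, AIC reported.
Selection runs on the full sample before LOO-CV — as in the original
analysis — which is optimistic; a nested mode re-selects within every
training fold. The LOO probability threshold is 0.5 with smoker as the
positive class; AUC is the concordance probability with half credit for
ties. Accuracy is tested with the exact one-sided binomial test (default
chance 0.5; other chance levels via `p0`) and an exact two-sided 95%
Clopper-Pearson interval. Note a selection-rate caveat: with m pure-noise
candidate features, BIC at n = 40 selects a spurious feature with
familywise probability ≈ 1 − (1 − q)^m, q ≈ 0.055 per feature, so "BIC
almost always keeps the null model" holds per candidate, not for large
candidate sets.

## Power analysis

Exact by default: power = P(X ≥ k* | n, p₁) with k* the smallest count
satisfying P(X ≥ k | n, p₀) ≤ α; simulation mode draws Binomial(n, p₁)
replicates and must agree within Monte-Carlo error. At n = 40, α = 0.05,
p₀ = 0.5: k* = 26 (65%), and power at p₁ = 0.70 is 0.807. Because the test
is discrete, power at p₁ = p₀ is ≤ α (conservatism), and a design can be
"unattainable" (n = 1 has no significant count); this is reported
explicitly rather than erroring.

## Problem sizes used in the test suite

Unit and integration tests run the raw tier at reduced scale (1–4
participants per group, 8–30 PV trials) — enough to exercise every QC
rule — while calibration claims use the bin tier at full scale: 200 null
datasets × 1,000 permutations for the familywise error rate, 40 replicates
for injected-cluster recovery, 100 replicates for the classifier
accuracy band, and 1,000 participants per group for effect-mean recovery.
These sizes give binomial/Monte-Carlo standard errors small enough for the
3-SE assertions used throughout.

## Known limitations

* The ramp amplitude and noise SDs are calibration choices, not measured
  quantities; only the group effect means/SDs and the trial structure are
  anchored to the published design.
* The gaze simulator produces idealised fixation sequences; the fixation
  detector's behaviour on saccade-rich or noisy data is validated only
  against its own sample-wise oracle, not against human recordings.
* Cluster p-values are valid under exchangeability of participants between
  groups; covariate imbalance is not modelled.
* An optional adapter for real eye-tracker exports is out of scope; the
  TSV contract documented in `io.py` is the only ingestion path.
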