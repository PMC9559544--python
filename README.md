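# pupilbias

Analysis tooling for pupillometric and gaze-based markers of attentional
bias toward nicotine-related stimuli (NRS), built for two-task eye-tracking
designs: a **dot-probe task** (DPT; two lateral images, a probed target
after a 1,500-ms SOA) and a **passive-viewing task** (PV; a 1-s scrambled
baseline followed by 3 s of foveal image presentation at 600-Hz binocular
pupil recording).

The package covers the full path from raw samples to inference:

* **`synthgen`** — synthetic participants with a known group structure:
  600-Hz binocular PV/DPT sample streams, blink/artifact/implausible-value
  missingness, trial-response tables, and the stimulus-image utilities
  (luminance normalisation to mean 0.4 / SD 0.15, pixel-shuffle scrambles).
* **`pupilprep`** — PV preprocessing: binocular merge (both eyes required),
  2–7-mm plausibility filter, >40% missing-trial and <50% valid-participant
  rejection, linear gap interpolation, zero-phase low-pass, 25-ms median
  binning, per-participant z-transform, realignment to image onset, and
  NRS−control difference curves.
* **`gazedpt`** — DPT bias scores: RT bias (control − NRS for correct
  responses after discarding practice and <100-ms anticipations), dwell-time
  bias, and first-fixation bias from a velocity-based fixation detector
  (≥40-ms fixations).
* **`clusterperm`** — cluster-based permutation tests on binned time
  series (Welch two-sample or one-sample pointwise t, cluster-mass
  statistic, relabeling / sign-flip null, exhaustive enumeration for small
  groups).
* **`classifiersuite`** — best-subset logistic selection by BIC/AIC,
  leave-one-subject-out cross-validated classification of smoking status,
  concordance AUC, and exact binomial inference with Clopper-Pearson
  intervals.
* **`powerstats`** — exact and simulated power for the one-sided binomial
  design, Welch t-tests, Pearson correlations with Fisher-transform CIs,
  and the Fisher z comparison of two correlations.
* **`io` / `cli`** — TSV readers/writers, run manifests with checksums,
  and the `pupilbias` command-line pipeline
  (`simulate / preprocess / fixations / features / cluster / classify /
  power / all`).

## The statistical core

Pupil traces are standardised within participant,
`z = (x − μ̂ᵢ) / σ̂ᵢ`, binned at 25 ms, realigned by subtracting the first
image-epoch sample, and contrasted as `Δ(t) = z̄_NRS(t) − z̄_control(t)`.
Group differences in `Δ(t)` are tested with a cluster-based permutation
test: per-bin Welch t statistics are thresholded at the two-sided pointwise
α = 0.05 critical value, consecutive same-sign suprathreshold bins form
clusters scored by their mass `Σt`, and each observed mass is referred to
the permutation distribution of the maximal null mass
(`p = (b + 1)/(B + 1)`). The cluster-window mean of `Δ` then serves as the
pupil feature in a leave-one-subject-out logistic classifier whose accuracy
is tested with the exact one-sided binomial test; a-priori power for that
design is `P(X ≥ k* | n, p₁)` with `k*` the smallest count for which
`P(X ≥ k | n, 0.5) ≤ α`.

## Worked example

```python
import pandas as pd
from pupilbias import SimConfig
from pupilbias.synthgen import simulate_difference_curves
from pupilbias.clusterperm import permutation_test
from pupilbias.classifiersuite import loo_cv
from pupilbias.powerstats import min_significant_count, binomial_power

cfg = SimConfig(n_per_group=20, seed=42)      # calibrated group effects
curves, groups, ids = simulate_difference_curves(cfg)

res = permutation_test(curves[groups == "smoker"],
                       curves[groups == "nonsmoker"],
                       n_perm=5000, seed=42)
best = min(res.clusters, key=lambda c: c.p_value)
print(f"cluster {best.start_ms:.0f}-{best.end_ms:.0f} ms, "
      f"mass {best.mass:.1f}, p = {best.p_value:.4f}")

lo, hi = cfg.effect_window_bins()
features = pd.DataFrame({"pupil_bias_z": curves[:, lo:hi].mean(axis=1)},
                        index=ids)
cv = loo_cv(features, (groups == "smoker").astype(float),
            subset=("pupil_bias_z",))
print(f"LOO accuracy {cv.accuracy:.2f} (AUC {cv.auc:.2f}), "
      f"binomial p = {cv.binomial_p:.3f}, "
      f"CI95 [{100*cv.ci95[0]:.1f}, {100*cv.ci95[1]:.1f}]%")

crit = min_significant_count(40)
print(f"design: k* = {crit.k}/40 ({crit.accuracy_percent:.0f}%), "
      f"power at true accuracy 0.70 = {binomial_power(40, 0.70):.3f}")
```

Output:

```
cluster 800-2850 ms, mass -260.6, p = 0.0022
LOO accuracy 0.65 (AUC 0.70), binomial p = 0.040, CI95 [48.3, 79.4]%
design: k* = 26/40 (65%), power at true accuracy 0.70 = 0.807
```

The permutation test localises the group difference to the 800–2,850-ms
window where the generator placed it (smokers constrict, non-smokers
dilate to NRS); the pupil feature alone classifies 65% of held-out
participants, exactly the smallest accuracy that beats chance at n = 40
(p = 0.04); and the design reaches 80.7% power when the true accuracy is
0.70.

The same pipeline runs from the shell:

```sh
pupilbias all --simulate --seed 7 --nperm 1000 --out runs/demo
```

## Documentation

See `docs/methods.md` for the modelling assumptions, the synthetic-data
generator's calibration, numerical choices, and known limitations.
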