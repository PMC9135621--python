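# Methods

## Overview

`ketsim` implements a template-matching analysis of thalamic functional
dysconnectivity. A spatial template of a drug-induced dysconnectivity
pattern is derived from within-participant contrasts of seed-based
connectivity in a pharmacological challenge arm; individual participants in
independent clinical cohorts are then scored by correlating their
normative-deviation connectivity maps with that template ("similarity
coefficients"), and the coefficients enter group and symptom-severity
models. Because clinical fMRI data of this kind cannot be shared, the
package ships a synthetic-data generator that plants exactly the structure
every downstream stage assumes, so the full pipeline is testable end to
end.

## Seed-based connectivity

The seed is defined by thresholding a probabilistic atlas map at
probability ≥ 0.80 (a stringent cut intended to exclude extra-thalamic
tissue). The seed time-series is the unweighted spatial mean over seed
voxels, taken from the unsmoothed input; optional spatial smoothing applies
to voxel series only. Each run's voxel time-series is regressed by OLS on
`[seed | nuisance]`, where the default nuisance set is an intercept and a
linear drift, with user-supplied columns (e.g. task regressors or motion
parameters) appended. The map of seed coefficients is the run's beta map.
No prewhitening or AR noise model is fitted: OLS is the implemented
contract, and the beta maps feed only linear fixed-effects combinations,
which are unbiased regardless of serial correlation. Voxels with
zero-variance series get beta 0 and are dropped from the analysis mask (the
count is logged rather than raised, since padded or out-of-brain voxels are
routine).

## Fixed-effects contrasts

Sessions have two infusion phases of three runs each (saline first, drug
second). Runs within a phase are averaged without variance weighting — runs
are equal length, so inverse-variance weights would differ only by noise.
The within-day contrast is mean(late) − mean(early); the between-day
contrast differences the active-drug day's within-day contrast against the
placebo day's, cancelling run-order effects by construction. Any non-empty
subset of a phase may be averaged, which reproduces the documented fallback
of contrasting a single late run against a single early run when runs are
dropped for artifacts.

## Group inference

Per voxel, the group statistic is the one-sample t across participants'
contrast maps, `t = mean / (sd/√n)`, df = n − 1. t-maps convert to z-maps
through quantile composition, `z = Φ⁻¹(F_t(t; df))`, evaluated via log tail
probabilities (`t.logsf` composed with `ndtri_exp`) so that extreme
statistics convert without underflow; the transform is odd and strictly
increasing by construction.

Cluster-extent inference uses a two-tailed cluster-defining threshold
(default |z| > 3.29, two-tailed p < 0.001). Positive and negative
suprathreshold voxels are labelled separately with face (6-neighbour)
connectivity — the conservative choice; 18/26 are available. Cluster-level
family-wise error is controlled by a sign-flipping permutation null of the
maximum cluster size over both signs: under the null of a symmetric
zero-mean effect, flipping each participant's map sign is exchangeable, and
each candidate cluster's corrected p is `(1 + #{perm max ≥ size}) / (1 +
n_perm)`. Because the voxelwise sum of squares is invariant under sign
flips, every permutation t-map needs only the flipped mean, making the null
exact and cheap. Permutations are seeded (default 20220414) for
reproducible runs. A Gaussian-random-field correction was deliberately not
implemented: the permutation test is assumption-light and exactly testable,
and its family-wise error is verified empirically (see below). The CDT maps
monotonically from z-space to t-space per df, so permutation thresholding
happens in t-space without per-permutation z conversion.

ROI means are unweighted averages over each significant cluster's voxels.
The three-condition comparison is a classical one-way within-subject ANOVA
(subjects × conditions decomposition, subject as blocking factor), with
two-sided paired t follow-ups; the per-ROI ANOVA p-values are BH-FDR
adjusted across the ROI family. No sphericity correction is applied by
default (three conditions, small n); exact zero between-condition variance
returns F = 0, p = 1. Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests` behind the package's `fdr_bh`
surface.

## Normative deviation maps

The HC reference regression is fitted per voxel on controls only — the fit
rejects any non-HC row. Two designs are supported: site (saturated
cell-means dummy coding; every site needs ≥ 2 controls) and linear age
(intercept + centred age). "Standard error of the regression" is the
residual standard error `√(RSS/(n_hc − k))`, not the prediction SE with
leverage: this matches the estimator named by the deviation-score
definition and yields unit-variance held-out control deviations
asymptotically. Deviation maps are `(observed − predicted)/residual SE`,
NaN outside the usable mask (voxels with near-zero residual variance are
masked). Scoring a covariate level unseen in the fit (a new site) is an
error, not an extrapolation.

## Similarity coefficients

The template is the unthresholded group-level contrast z-map. Template and
deviation maps are flattened in a fixed lexicographic order (first axis
fastest — Fortran-order ravel) over a single cohort mask: the intersection
of the template's finite voxels with every participant's finite voxels,
computed once per cohort so every vector has identical length and
ordering. The similarity coefficient is the Pearson correlation of the two
vectors; it is Fisher r-to-z transformed (`atanh`) for all group
statistics. Whole-map intersection masking is the implemented contract;
gray-matter restriction is the caller's responsibility via the map masks.

## Group and symptom statistics

Group models are linear models of Fisher-z similarity on group, sex, and
(when multi-site) study site, fitted with explicit treatment-coded design
matrices. Each model starts with a group × sex interaction; a
non-significant interaction (α = 0.05, two-sided) is dropped, and effects
are reported from the main-effects model. This reproduces the shared-df
reporting style of multi-site studies: with two groups, sex, and seven
sites at n = 361 the residual df is 352; with three groups and sex at
n = 204 it is 200. Pairwise group contrasts and within-group
tests-against-zero use estimated marginal means (predictions averaged with
equal weights over sex and site levels) with the model residual variance
and df; pairwise p-values are BH-FDR adjusted across the three group
pairs. Cohen's d is the covariate-adjusted mean difference divided by the
model residual SD, which reduces exactly to classical pooled-SD d in the
two-group no-covariate case.

Symptom domain scores are the item sum plus the global severity rating;
only participants with a global rating ≥ 2 (at least mild) enter a
domain's model. A domain-wide square-root transform fires when the sample
skewness of included raw scores exceeds 1.0 (the transform itself is part
of the analysis contract; the threshold is this package's choice, applied
before modelling). Scores and similarity coefficients are standardised
within the included subsample, so the reported slope is a standardised β
(a raw slope in score units per Fisher-z unit is reported alongside). Each
model starts with a similarity × sex interaction, dropped when
non-significant (α = 0.05), in which case the common slope is reported;
otherwise per-sex slopes are fitted. When a model fits essentially
perfectly (residual variance ~0), the interaction t-statistic is numerical
noise, so the interaction is judged by its coefficient magnitude instead.
BH FDR runs across the domain family — SAPS and SANS domains form one
family of eight tests, SOPS its own family of four — and outputs record the
family and its size. The antipsychotic-dose confound check is a Spearman
rank correlation (midrank ties) between CPZeq (mg/day, an input column;
dose conversion is out of scope) and the similarity coefficients, chosen
for the non-normality of dose distributions.

## Synthetic data

The generator's defaults are the study conditions for all shipped tests.

* **Grid and sessions.** 24×24×24 voxels, TR 2 s, 210 volumes per run,
  three runs per infusion phase. The seed is a central probabilistic blob
  (19+ voxels at the 0.80 cut); the ground-truth dysconnectivity pattern is
  a positive "sensory" lobe plus a weaker negative lobe, standardised to
  unit spatial SD over the grid.
* **BOLD runs.** Every voxel follows `w_v·s(t) + drift + noise` where
  `s(t)` is a smooth latent series shared by seed voxels (`w = 1` in the
  seed). Under active ketamine the coupling in template-positive voxels
  increases in proportion to the template value, peaking at
  `coupling_delta` = 0.5; lamotrigine pre-treatment attenuates the increase
  by a configurable fraction, default 0 (no attenuation, matching the
  finding the pipeline is built to test). Noise is white with SD 1.0 plus a
  random per-voxel linear drift. No hemodynamic convolution or scanner
  artifact model is attempted: the simulator exists to exercise the
  estimators, not to fool a radiologist.
* **Clinical maps.** `map = baseline + site offset + age slope·(age −
  reference) + λᵢ·template + noise`, all spatial fields Gaussian-smoothed
  white noise (σ = 1.5 voxels) rescaled to target SDs, so cluster inference
  sees realistic spatial autocorrelation. Loadings are λᵢ ~ N(λ_g, 0.3)
  with group means HC 0, CHR-P 0.15, ESZ/SZ 0.3. With map noise SD 1.5
  (per pattern-SD unit), these produce similarity coefficients spanning
  roughly −0.4…0.6, group mean Fisher-z near 0 / 0.06 / 0.12, and
  patient-vs-control effect sizes near d ≈ 1 — the regime reported for
  chronic-illness samples.
* **Symptoms.** A domain's item sum is `round(max(0, 8 + slope·fisher_z +
  N(0, 3)))` split multinomially over five items; only the hallucination
  domain is coupled by default (slope 6 score units per Fisher-z unit,
  giving a standardised β near 0.3). The global rating is drawn
  independently with 30% of ratings below 2, exercising the inclusion
  filter without inducing selection bias.
* **Seeding.** One root seed (default 20220414) fans out into keyed
  substreams per participant, stage, and replicate, so outputs are
  bit-reproducible and cohorts extend without reshuffling.

What the generator does not emulate — richer physiological nuisance
structure, motion, registration error, hemodynamics, site differences in
anything but additive offsets — bounds what passing tests show: they verify
the estimators and their error control under the stated model, not
robustness to real-world artifacts.

## Replicate studies and problem sizes

`ketsim.studies` packages the standing evidence, with sizes chosen as
desk-scale defaults:

* **Calibration** — site model fitted on 200 simulated controls, scored on
  200 held-out controls; pooled deviation mean within ±0.1 and SD within
  0.9–1.1.
* **Error control** — 200 null replicates of 18 zero-effect contrast maps
  on the 24³ grid, 500 sign-flip permutations each; the fraction of
  replicates with any surviving cluster sits within binomial bounds of the
  nominal 0.05. Null replicates draw between-day contrast maps directly as
  smooth zero-mean fields rather than simulating full BOLD sessions — the
  contrast of a no-effect session is exactly such a field, and the direct
  draw is what makes replicate studies tractable.
* **Parameter recovery** — 100 replicates at cohort sizes 85/45/74 recover
  the planted loading order HC < CHR-P < ESZ in ≥ 95% of runs; 50
  replicates recover the planted hallucination slope within two Monte-Carlo
  standard errors.

## Numerical conventions

Voxel indices are 0-based; world coordinates follow the NIfTI affine
(RAS+). All volumes in an analysis must share one grid and affine; nothing
resamples, mismatches fail fast naming the offender. Statistic maps carry
NaN outside their masks and every consumer folds NaNs into mask logic.
Permutation p-values include the identity term (+1 numerator and
denominator), so they are never zero. Exact-tie degeneracies (identical
RM-ANOVA conditions, perfect regression fits) are resolved toward the null
rather than left to floating-point noise. Pipeline outputs carry JSON
sidecars with the configuration hash (location-independent) and seed; run
manifests list SHA-256 digests per output and contain no timestamps, so a
run is a pure function of its configuration.
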