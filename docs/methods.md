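# Methods

This note records what the package computes, the assumptions behind each
stage, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate.

## Feature space

The default schema holds 101 regions: the 68-region Desikan-Killiany
cortical parcellation (34 per hemisphere) plus 33 ASEG structures (12
bilateral pairs — lateral and inferior-lateral ventricles, cerebellar white
matter and cortex, thalamus, caudate, putamen, pallidum, hippocampus,
amygdala, accumbens, ventral diencephalon — and 9 midline structures: 3rd
and 4th ventricles, CSF, brain stem, five callosal segments). ASEG naming
varies slightly across FreeSurfer versions; users should verify the shipped
list against their own aseg output, and may supply any custom schema of any
length — all downstream code is parameterized by the region count. Each
region belongs to exactly one high-level group (frontal, temporal, parietal,
occipital, insula, cingulate, subcortical, cerebellum, corpus callosum,
ventricles), used by the heterogeneity analysis.

All modelling operates on *relative* volumes (raw volume / total
intracranial volume), which removes head-size variation. Sex is stored as
F/M in files and coded F=0, M=1 internally. Missing optional fields
(diagnosis, symptom scores) are explicit nulls and never imputed.

## Cohort cleaning

Four rules, in order:

* **Quality.** Scans with probability-unusable strictly greater than 0.7 are
  discarded; 0.7 itself is kept (strict inequality, boundary-stable).
* **Age.** The closed window [20, 80] years is kept.
* **Undersampling.** Within one nominated scanner, each age bin keeps at
  most 55 participants by a seeded uniform draw. Bin width defaults to 5
  years (the width of an "age group" is a free choice here); the draw is
  made on id-sorted rows so results are independent of row order.
* **Outliers.** Within each scanner, participants with ≥ 10 relative volumes
  strictly beyond 3 sample SDs (ddof = 1) of the per-region mean are
  excluded; means and SDs are recomputed and the pass repeats until nobody
  is excluded. The procedure terminates because the retained set strictly
  shrinks. Under a clean Gaussian cohort the expected exclusion count is the
  binomial tail P(≥ 10 of 101 beyond 3σ) ≈ 1e-13 per participant, i.e.
  essentially never — the rule only fires on genuinely aberrant rows.
  Scanners with fewer than 3 retained rows are skipped.

## Scanner harmonization

**ComBat.** Parametric empirical-Bayes ComBat in the standard formulation:
least-squares fit of per-batch means plus covariate effects; standardization
by the pooled residual variance; per-batch location (γ) and scale (δ)
estimates shrunk toward normal / inverse-gamma priors whose hyperparameters
come from the across-feature moments; iterative conditional updates to a
relative tolerance of 1e-6. Covariate effects (age, sex) are estimated
jointly and restored after correction, so biological signal is preserved.
An `eb=False` switch gives the no-shrinkage (diffuse-prior) limit used as an
oracle in the tests. Applying the model to a batch not seen at fit time is
an error that points the user to the IQM-based harmonizer.

**IQM-based correction prediction.** One random forest per region learns to
map image quality metrics plus covariates to the ComBat correction
(corrected − uncorrected) on the training rows; at apply time only IQMs and
covariates are needed, no batch label, so unseen scanners can be corrected.
Two variants are fitted with different covariate sets — {age, sex} for the
outlier path and {sex} for brain age — because the two downstream models
control for different biology. Covariates are included as predictors
alongside the IQMs (the forest can then modulate corrections by them); this
is one of two defensible readings of "controlling for" and is flagged here
as a design choice. Defaults: 500 trees, default depth, seeded per region.
Predicted corrections are an interpolation over the training IQM range;
rows with any IQM outside the training [min, max] envelope are flagged
out-of-range but still corrected (a warning, not a refusal), since
extrapolated corrections degrade gracefully rather than failing outright.

## Outlier model

A small adversarial autoencoder on robust-scaled relative volumes:
encoder 101→100→50→20, mirrored decoder, discriminator 20→50→25→1,
leaky-ReLU (slope 0.2) hidden units, linear outputs, implemented directly in
numpy with manual gradients and Adam. Each minibatch (size 64) runs three
updates: encoder+decoder on mean squared reconstruction error (lr 1e-3);
discriminator on prior-vs-encoding cross-entropy; encoder on the
non-saturating generator objective. Training runs up to 200 epochs with
early stopping on a 10% validation split (patience 20), keeping the
best-validation parameters, and is fully seeded.

Two numerical choices matter here:

* **Adversarial balance.** The discriminator takes 5 updates per minibatch
  at lr 1e-3 while the encoder's adversarial update uses lr 5e-4. With a
  single slow discriminator update the latent distribution visibly drifted
  from the prior (per-dimension means near ±1.4); with this schedule
  held-out encodings match the standard Gaussian to within ±0.3 in mean and
  [0.5, 1.5] in SD at n = 500.
* **Error space.** Inputs are robust-scaled per region (median/IQR,
  linearly-interpolated quantiles) before the network, and squared errors
  are computed in that scaled space; otherwise large structures would
  dominate the overall mean error.

Per-region errors are e_j = (x_j − x̂_j)²; the overall error is their mean.
The OIS scaling subtracts the training median and divides by the training
IQR, region-wise and for the overall error, so training OIS has median
exactly 0 and IQR exactly 1; scores are not clamped (below-median errors go
negative). Categories use the published cut-offs (0.26, 1.1, 2.3); a
quantile-based `derive_cutoffs` (quartiles of the positive training tail) is
provided as an opt-in alternative but never silently replaces the published
values, whose derivation ("centiles grouped into quartiles") is ambiguous
in prose — the constants are treated as authoritative.

## Brain age

Features are z-scaled per region (the scaler is part of the model), then a
linear ε-SVR (ε = 0.1, tol = 1e-3) is fitted. C is selected by seeded,
shuffled 10-fold cross-validation over the seven-value grid
{2⁻⁷ … 2¹} scored by mean absolute error; ties break toward the smaller C
(stronger regularization). BAG = predicted − chronological age;
"normalized according to the train set" is interpreted as z-scoring with
the training BAG mean and SD, which makes healthy training data center at 0
and preserves group differences up to the scale factor. No age-bias
correction is applied in the headline outputs: shrinkage toward the mean
age makes young ages over- and old ages under-predicted, so raw BAG
correlates negatively with age. `residualize_bag_on_age` is provided for
downstream analyses that want the dependence removed; it is off by default.
MAE is reported as mean ± SD of absolute errors and can be computed on any
split (cross-validated and resubstitution estimates differ; both are just
calls to `evaluate_mae`).

## Cohort statistics

* Group tests gate on Shapiro-Wilk at α = 0.05 for *both* groups; the
  parametric branch is the equal-variance independent-samples t-test, the
  fallback the two-sided Mann-Whitney U. A constant group (Shapiro
  undefined) falls back with a note.
* Mann-Whitney U is reported for the first group (pairs won + half-ties);
  p-values are exact for min(n) ≤ 8 without ties, otherwise the normal
  approximation with tie and continuity corrections.
* Region-wise p-values are Benjamini-Hochberg adjusted (step-up, capped at
  1, order restored).
* Symptom scales are min-max normalized to their instrument's *allowed*
  range and then z-scored within sample (ddof = 0), making different
  instruments poolable; raw scores outside the allowed range are an error.
* Deviation–symptom correlations gate Pearson vs Spearman on the Shapiro
  test of the symptoms, per the convention for these analyses.
* Heterogeneity is the mean (and SD) of pairwise cosine similarities of
  OIS vectors, overall and per region group. Cosines are computed on the
  signed OIS values, so negative similarities are possible and reported
  as-is; pairs involving an all-zero vector are skipped and counted.
* Bootstrap CIs for median differences use a seeded percentile bootstrap,
  1000 repetitions by default.

## Synthetic cohorts

The simulator draws, per participant: age uniform on [20, 80]; sex
Bernoulli(½); TIV log-normal with a sex-dependent location (1.55e6 mm³ male,
1.38e6 female, log-SD 0.07, typical of adult FreeSurfer output). Relative
volumes follow group-level baselines (cortical ≈ 3–4e-3 of TIV, cerebellum
8e-3, callosal segments 6e-4) with mild negative linear-plus-quadratic age
slopes for tissue (≈ −0.2 to −0.3%/year) and a strong positive slope for
ventricles (+1.5%/year), small multiplicative sex offsets, and independent
Gaussian noise (SD 6% of baseline). Scanner effects are driven by a latent
per-scanner quality factor: additive shifts proportional to it (default SD
0.4 within-scanner noise units), log-normal multiplicative factors, and 8
named IQMs whose means load linearly on the same factor — so IQMs carry
exactly the information the correction-predicting forests need, by
construction. The probability-unusable score is a per-scanner Beta mixture
with a configurable fraction of "bad" scans above 0.7. Disease injection
multiplies chosen regions by (1 − fraction·severity) — negative fractions
model enlargement — with severity |N(mean, sd)| per patient driving a noisy
linear symptom score.

What this does *not* emulate: realistic inter-regional covariance beyond
the low-rank age/sex/scanner structure, non-linear IQM-effect links,
site-by-age interactions, longitudinal repeats, or segmentation failure
modes. Tests passing on these cohorts show the pipeline recovers the
effects it models under its own assumptions; they say nothing about
FreeSurfer accuracy or about disorders whose signature is not a
multiplicative regional volume change.

## Problem sizes and determinism

Defaults were chosen so the full pipeline (simulate → prep → harmonize →
train → score → analyze → report) runs in about a minute at n = 500 on one
CPU; the test suite uses cohorts of 100–700 and reduced forest sizes, which
are ample for the injected effect sizes. Everything is seeded through
`numpy.random.Generator` and runs single-threaded, so a fixed config and
seed reproduce every output file byte for byte; the pipeline records the
seed and a config hash in each summary.

## Known limitations

* ComBat is the parametric variant only; heavy-tailed batch effects would
  favor the non-parametric version, which is out of scope.
* The correction-predicting forests interpolate within the training IQM
  envelope; corrections for genuinely unusual scans (flagged out-of-range)
  are extrapolations of a piecewise-constant model.
* The AAE is a point model: no uncertainty on OIS is produced.
* The brain-age model is linear by design; its headline outputs retain the
  age bias discussed above.
* Model persistence uses JSON metadata plus npz/joblib payloads; joblib
  files are not portable across major scikit-learn versions.
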