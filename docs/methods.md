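# Methods

`phenomap` implements a comparative phenotyping pipeline for chronic
obstructive pulmonary disease (COPD) on paired inspiratory/expiratory
chest CT: voxel-wise parametric response mapping (PRM), patch-based
density anomaly scoring on latent features, latent-space structure
analysis (PCA retention, clustering, t-SNE), and the cohort-level
statistical comparison layer.  Because multi-site paired-CT cohorts such
as COPDGene cannot be redistributed, every stage is driven by a synthetic
cohort generator with known voxel-level ground truth; all empirical
claims made by the test suite are claims about that generative model, not
about real CT.

## Synthetic paired-CT cohort

Each subject carries an inspiratory HU grid, a voxelwise-aligned
("pre-registered") expiratory HU grid, a binary lung mask, an ordinal
disease stage (never-smoker `control`, then `GOLD0`–`GOLD4`), and a study
site.  Deformable registration is deliberately out of scope: the
expiratory grid is emitted on the inspiratory lattice.

**Geometry.** The lung is two disjoint ellipsoids (left/right) on a
64×64×48 voxel grid at 2.5 mm isotropic spacing by default (≈67k lung
voxels).  Lesions are spherical blobs with uniform random radii of 3–7
voxels, seeded at random lung voxels until the per-subject target burden
is met; the final blob is trimmed by distance from its centre so the
realized lesion fraction equals the drawn target exactly.

**Burdens.** Per-stage mean lesion fractions for emphysema and
functional small-airway disease (fSAD) default to the class means of a
large multi-site COPD cohort (emphysema 0.3→29.5 %, fSAD 7.1→45.1 % from
controls to GOLD 4, divided by 100); per-subject targets are Beta draws
with concentration 30 around those means, which reproduces the monotone
stage trend with realistic between-subject spread.  A jointly extreme
draw is capped at 95 % total lesional lung, preserving the
emphysema/fSAD ratio; a *configured* target above 0.95 is an error.

**HU models.** Each tissue class samples HU from a truncated normal
whose truncation bounds lie strictly inside the PRM box the class is
meant to occupy (e.g. emphysema: inspiration N(−975, 12²) on
(−999.5, −950.5), expiration N(−945, 20²) on (−999.5, −856.5)).  This
makes PRM class recall on ground truth a sharp correctness check rather
than a statistical one.  No attempt is made to model CT noise texture,
airways, vessels, or respiratory motion; consequences for interpretation
are noted under *Limitations*.

**Clinical covariates.** Every clinical variable is a linear function of
the two lesion fractions plus a per-site random intercept and Gaussian
noise, clipped to its physiological range — e.g. FEV1 %pred =
98 − 160·emph − 70·fsad + site + N(0, 8²).  TLC is generated as FRC plus
an inspiratory reserve term so TLC ≥ FRC holds by construction, and
FRC/TLC is derived.  Controls have smoking duration 0 and status 0.  The
site intercept SD is one `site_sd` knob (default 3, FEV1-percent units)
scaled per variable by the ratio of that variable's noise SD, so the
mixed-model stage sees a genuine shared site effect in every outcome.
These coefficient choices are stand-ins designed to reproduce the
*signs* and rough strengths of the published burden–function
correlations, not estimates of any real cohort.

**Determinism.** The master seed spawns independent `SeedSequence`
substreams per subject (and one for site effects), so cohorts are
byte-identical across runs and subjects are independent of cohort size
ordering.

## Parametric response mapping

Voxels inside the lung mask are classified jointly on (inspiratory,
expiratory) HU:

| class | inspiration | expiration |
|---|---|---|
| Emphysema | [−1000, −950] | [−1000, −856) |
| fSAD | (−950, −810] | [−1000, −856) |
| Normal | (−950, −810] | [−856, −500] |
| Excluded | everything else | |

The boundary-closure convention (−950 HU belongs to the emphysema box on
inspiration; −856 HU belongs to the normal box on expiration) is a
declared tie-break, tested explicitly.  Relative class volumes are
percentages of *classified* voxels (the three classes sum to 100);
the excluded share is reported relative to all lung voxels.  LAA-950
(inspiration) and LAA-856 (expiration) use strict `<` thresholds.

## Patches and features

Cubic patches (default 50³ voxels) are tiled with 20 % overlap
(stride = round(0.8·size) = 40), the final origin per axis clamped so the
last patch ends at the volume edge; axes shorter than the patch side
shrink the patch on that axis when clamping is enabled.  Patches with
lung fraction below `min_lung_fraction` are dropped.  The default
threshold is 0.2: with ellipsoidal lungs occupying ≈30 % of the grid, a
50³ patch on a 64³-scale grid tops out near 0.45 lung fraction, and 0.2
keeps the union of retained patches covering >70 % of lung voxels (the
coverage the pipeline asserts).

The default featurizer is a deterministic paired-HU histogram: 64-bin
probability histograms of lung-voxel HU over [−1024, −400) for each
phase, the phase means/SDs (scaled 1/1000), and the patch-level
LAA-950/LAA-856 fractions, zero-padded to a configurable dimension
(default 512).  A small self-supervised contrastive encoder is available
as an alternative featurizer: a two-layer NumPy MLP on pooled 8³ patch
pairs trained with an NT-Xent objective on two stochastic views per
patch (axis flips, random crop-resize, HU jitter), Adam, temperature
0.5.  It demonstrates the contrastive training dynamics at desk scale
and makes no claim of equivalence to large pretrained 3D encoders.

## Anomaly scoring

The reference ("normality") set is all patches with <1 % emphysema
(patch-level LAA-950 on inspiration) from subjects without airflow
obstruction (controls and GOLD 0).  Features are optionally
PCA-whitened to at most 32 dimensions (directions with numerically zero
variance dropped), then a reference density is fitted: a full-covariance
Gaussian, or a Gaussian mixture with the number of components chosen by
minimum BIC over k = 1–8 (covariance ridge 1e-6).  Patch anomaly scores
are negative log-likelihoods (nats) under this density; the patient
score is the mean patch score (median/max selectable).  Anomaly map
volumes average the scores of all patches covering a voxel, then min-max
normalize to the 5th/95th percentiles of the cohort-wide patch-score
distribution, clipping to [0, 1]; non-lung voxels are 0, and degenerate
bounds (p95 ≤ p5) yield an all-zero map with a warning.

## Latent structure

PCA scores/loadings are computed on mean-centered, unscaled features.
Component retention uses Horn's parallel analysis on the correlation
scale, where eigenvalues of standard-normal surrogate data are
comparable: a component is retained while its correlation-scale
eigenvalue exceeds the 95th percentile (configurable) of the matching
eigenvalue from 100 same-shape standard-normal matrices, stopping at the
first failure.  The Kaiser count (correlation eigenvalues > 1) is
reported alongside; the model retains max(1, Horn count).

Clustering compares mini-batch K-means (batch 1000) and full-covariance
Gaussian mixtures over k = 2–8, scoring each fit with silhouette
(maximize), Davies–Bouldin (minimize) and Calinski–Harabasz.  One
published description targets Calinski–Harabasz for *minimization*,
which contradicts the index's construction (between/within variance
ratio; larger is better-separated); this package maximizes it and
records the discrepancy here.  Selection is the lowest mean rank across
the three metrics, ties broken toward smaller k, then method order.
Degenerate fits (empty clusters) are retried with fresh seeds.
Per-subject cluster volumes are the fractions of a subject's patches per
cluster (rows sum to 1).  Cluster maps assign each lung voxel the label
of the nearest patch centre, ties to the lowest label.

t-SNE is fitted on an evaluation subset and test points are placed by
inverse-distance-weighted barycenters of their 10 nearest fit-set
neighbours in feature space.  This is a visualization device only; no
quantitative claims rest on the embedding geometry beyond a
class-separation sanity check.

## Statistics

*Jonckheere–Terpstra.* The trend statistic counts concordant
cross-group pairs with ties counting ½; p-values use the normal
approximation with the standard tie-corrected variance (three-term
formula over tie-group sizes).  An optional Monte-Carlo permutation
p-value is a mid-p estimator (permuted statistics equal to the observed
one count ½), consistent with the half-tie convention of the statistic;
for small samples the normal approximation tracks it to ≈0.01 in the
mid-range.  Identical-valued data raise a degenerate-data error.

*Tukey HSD* wraps the studentized-range implementation in statsmodels,
returning full-precision adjusted p-values and CIs (the printed summary
rounds to four decimals); scipy's independent implementation serves as a
cross-check in the tests.

*Correlations.* Pearson r with paired-case-resampling percentile
bootstrap CIs (default 10,000 resamples, seeded); degenerate resamples
(zero variance) are dropped.  Magnitude bands: <0.10 negligible,
0.10–0.39 weak, 0.40–0.69 moderate, 0.70–0.89 strong, ≥0.90 very strong.

*Dependent overlapping correlations.* Zou's (2007) CI for
r_jk − r_jh when both correlations share variable j, built from the
Fisher-z interval endpoints of each correlation and their estimated
co-dependence through r_kh.  |r| = 1 raises (Fisher divergence).
Significance is "CI excludes zero".

*Holm–Bonferroni* step-down adjustment (statsmodels), applied across the
correlation table when enabled.

*Mixed models.* Random-intercept (study site) linear mixed models fitted
by maximum likelihood (not REML) so nested models are comparable by
likelihood-ratio test: statistic 2Δlog L against χ² with df = number of
added fixed-effect columns.  Because the site-variance estimate can sit
on the boundary, fitting cascades lbfgs → Powell → Nelder–Mead and keeps
the best achieved log-likelihood.  Reported fit quality is the Nakagawa
& Schielzeth conditional R² — (fixed + random variance) / (fixed +
random + residual) — with an Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − p − 1) for the number of regressors; the
adjustment is isolated in one place so it can be swapped.  Smoking
status and sex enter as categoricals; sites carry random intercepts only
(no random slopes).

*Bland–Altman.* For non-constant bias, the bias is modelled by OLS of
the difference D on the average A (optionally after log transform);
default limits of agreement are the fitted line ± 1.96·SD of the OLS
residuals (constant width), with a variable-width option that regresses
|residuals| on A (× √(π/2) under normality).  On the log scale, pairs
with a nonpositive value in either method are excluded and counted — no
offset is added, keeping the transform faithful.

## Pipeline and problem sizes

The orchestrated pipeline (simulate → PRM → features → anomaly →
cluster → stats → report) writes each stage to plain files (NIfTI, CSV,
JSON) under its own subdirectory, validates its JSON config against a
shipped schema (unknown keys rejected), derives every stage seed from
the master seed, and is byte-deterministic: re-running the same config
reproduces identical statistics CSVs.  The default demo configuration is
10 subjects per stage on 64³ grids (60 subjects, 8 patches each), which
exercises every stage in well under a minute on one CPU; the test suite
uses 20- and 30-per-stage cohorts at the default 64×64×48 grid for the
calibration and trend checks.  These sizes were chosen as the smallest
cohorts at which the stage trends and calibration bounds are stable.

## Limitations

- The generator reproduces the *statistical* structure the pipeline
  assumes (monotone burdens, HU-box fidelity, linear clinical linkage,
  site effects), not CT physics. Passing tests therefore validate the
  algorithms and their couplings, not performance on real scans.
- HU truncation makes PRM recall essentially exact by design; on real
  CT, noise, registration error and partial-volume effects would blur
  class boundaries.
- The published data-dependent findings (specific correlation values on
  real cohorts, 85 retained components, a particular 4-cluster solution,
  fitted agreement coefficients, left/right asymmetry) are not
  reproduction targets at this scale.
- The contrastive encoder is a demonstration-scale stand-in; the
  histogram featurizer is the supported default.
- Cluster-count selection on histogram features of a synthetic cohort
  depends on the burden mixture; the pipeline reports the full selection
  table rather than promising a fixed k.
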