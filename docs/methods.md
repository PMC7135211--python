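# Methods

This note documents the models, conventions and numerical choices
behind `rimmune`, and what the synthetic validation does and does not
establish.

## The synthetic study

The package validates its analysis chain on simulated cohorts because
the kind of paired CT/expression data it targets cannot be bundled.
The generator (`rimmune.phantoms`, `rimmune.expression`) emulates the
features the analysis is sensitive to, with a single latent immune
state per sample tying the two modalities together.

**Image phantoms.** One quasi-ellipsoidal lesion per volume (axis
lengths jittered ±10% around `tumor_radius_mm`, default 8 mm, on a
32³ grid of 1 mm voxels). The intensity model is a radial profile plus
a texture field:

* a core at `core_mean_hu` (default 20 HU) carrying a
  Gaussian-correlated noise field (white noise smoothed to
  `texture_corr_len_mm`, default 2 mm, rescaled to `noise_sd_hu`,
  default 15 HU). An exponential warp `(exp(s·z)−1)/s`, re-standardized,
  injects histogram asymmetry via `histogram_skew_param`;
* a bright rim ring of thickness 3.25 mm ending at the mask boundary,
  with a sharp (0.25 mm) inner ramp and an outer sigmoid fall-off of
  width `margin_width_mm` (default 1 mm) centred on the boundary. The
  background mean equals the core mean, so an outward margin profile
  sees a step equal to the rim–core contrast (40 HU by default);
* latent states `(th1, th2, ctl) ~ i.i.d. N(0,1)`. The coupling
  parameter `coupling_beta` (HU per latent unit) shifts the rim–core
  contrast by `beta·th2` and scales the margin width by
  `exp(−0.01·beta·th2)`, clipped to [1/2, 2]. Both couplings are
  monotone in `th2`; the clip prevents extreme latents from erasing
  the rim altogether.

The rim thickness/inner-ramp/profile-length constants were fixed
jointly so that (a) the ring lies mostly inside the 2 mm shell used by
the delta features, making the delta-region mean track `th2` nearly
linearly (Pearson ≈ 0.9 at `beta = 45`), and (b) margin profiles still
see an inner plateau, so the logistic fit recovers the generating
amplitude within ~10% and width within ~10–25% on noiseless phantoms.

**Expression.** Values live on a log2-microarray-like scale: per-gene
baselines `N(6, 1)`, per-measurement noise `N(0, base_noise²)`
(default 1), and an additive shift `effect_size · latent` (default 2,
i.e. two noise SDs per latent unit) on the member genes of each of the
28 immune gene sets. Th1/Th2/cytotoxic sets use the sample's latents;
the other 25 sets fluctuate with their own independent latents. The
28-set panel itself is a synthetic stand-in (seeded random membership,
20 genes per set over 5 000); any GMT with the three designated sets
satisfies the pipeline contract.

**What passing does not show.** The phantoms have one lesion, no
scanner/protocol variation, no contrast-enhancement phases, isotropic
default spacing and Gaussian texture; the expression model has no
batch structure, probe effects or count noise. Results on this
generator demonstrate that the chain is *correct and sensitive* (it
recovers planted effects and stays at chance under the null), not that
any particular real-data accuracy will be achieved.

## Radiomic conventions

* **Catalog.** 239 features: physical 3, histogram 59 (11 statistics ×
  5 regions + p10/p25/p75/p90 of the whole lesion), shape 10, local 95
  (26 GLCM statistics × distances {1,2} voxels + 16 GLRLM + 16 GLSZM +
  5 NGTDM + 6 GLDM), LoG 63 (9 statistics × sigmas 0.5–3.5 mm in 0.5
  steps), fractal 3, sigmoid 6. The catalog is a YAML-serializable
  manifest; the census is enforced as a construction invariant.
* **Regions.** Inner/outer split by metric erosion: a voxel is inner
  when its Euclidean distance (mm, spacing-aware; volume edges count
  as background) to non-mask exceeds `rim_depth_mm` (default 2 mm).
  Delta values are seeded random pairings of equal-sized samples of
  outer and inner intensities (outer − inner); the value arrays are
  sorted before pairing so the draw depends only on the value
  multisets, keeping features translation invariant. deltaS is a
  seeded 50% subsample by default.
* **Moments.** Population conventions: variance `m2`, skewness
  `m3/m2^1.5`, kurtosis reported as excess (`m4/m2² − 3`). Zero
  variance yields missing skewness/kurtosis (logged), handled later by
  KNN imputation.
* **Discretization.** Fixed bin count (32) over the ROI min–max; a
  constant ROI collapses to a single level (GLCM becomes a point mass;
  IMC is 0 by convention; correlation 1 by convention).
* **Texture matrices.** 13 unique 3-D directions for GLCM/GLRLM,
  26-connectivity for GLSZM zones and the NGTDM/GLDM neighborhoods;
  matrices are merged over directions before statistics. All five
  families are checked against independent brute-force enumeration on
  ≤8³ fixtures to 1e-10.
* **LoG.** Scale-normalized (`sigma² · ∇²G`), sigma in physical units
  converted per axis. The sampled kernel's nonzero DC gain is
  subtracted (response to a constant is exactly zero); sub-half-voxel
  sigmas warn but compute.
* **Fractal.** Surface dimension: dyadic box-count ladder on the mask
  boundary, least-squares slope of log N vs log(1/ε); solid/flat
  fixtures recover 3 and 2 within 0.2. Intensity dimension by 3-D
  differential box counting with a denser ladder (2,3,4,6,8,…) so
  ~15-voxel lesions retain ≥3 ladder points. Lacunarity: gliding-box
  `var/mean² ` of mask occupancy at box size 3.
* **Sigmoid margin.** Profiles at up to 30 seeded boundary voxels
  (volume-edge voxels excluded), along outward normals from the
  gradient of the Gaussian-smoothed mask, sampled ±1.5 mm at half-voxel
  steps by trilinear interpolation; least-squares logistic fit with
  amplitude defined inside-minus-outside. Flat profiles (range
  < 1e-9) and non-converged fits are dropped; fewer than 20% usable
  fits marks all six features missing.

## Immune profiling

ssGSEA ranks a sample's genes descending (ties broken by stable input
gene order) and integrates `P_in − P_out` along the list, where `P_in`
accumulates in-set weights `(n − position)^alpha` (alpha = 0.25) and
`P_out` is uniform over out-of-set genes. Because the weights are
rank-based, scores are invariant under any strictly monotone transform
of the expression values. Matrix normalization divides by the global
max − min. PCA is column-centered (covariance-based) with the sign
convention that each component's largest-|loading| entry is positive.
Dichotomization uses strictly-greater-than-the-cohort-mean; an
all-equal score vector is a hard error rather than an arbitrary split.

## Modeling

* **Preprocessing** (in order, fitted on training data only and refit
  inside every bootstrap resample): drop zero-variance features → KNN
  imputation (k = 5) → per-feature Yeo-Johnson with maximum-likelihood
  lambda → center/scale to unit SD.
* **Classifiers.** LDA and Gaussian naive Bayes are implemented from
  their closed forms (shared-covariance Gaussian discriminant with a
  ridge-regularized inverse when the pooled covariance is singular;
  per-class independent Gaussians with variance smoothing). Penalized
  logistic (ridge), shrinkage discriminant, CART, bagged CART and
  random forest use scikit-learn; sparse discriminant analysis is
  ℓ1-penalized optimal scoring (lasso on a ±1 class indicator). All
  return a continuous score; "high" is the positive class.
* **0.632 bootstrap** (B = 25 default): per resample, fit
  preprocessing + model on the bootstrap sample, evaluate on the full
  training data (apparent) and the out-of-bag samples, combine
  `0.368·apparent + 0.632·oob`; report mean and SD of the per-resample
  combined values. Sensitivity/specificity use the Youden-optimal
  cutoff on the apparent scores of the same resample. Hyperparameters
  (small fixed grids) are chosen per resample by out-of-bag AUC.
  Single-class resamples or out-of-bag sets are skipped and logged.
* **Estimator optimism at p ≫ n.** With 239 features and ~100
  samples, every discriminant direction partially memorizes its
  training points, so the apparent term is optimistic and the null
  (no-signal) expectation of the combined AUC is ≈ 0.61 rather than
  0.50 — diagonal-loading strength barely moves this, since even the
  class-mean difference direction is noise-fit. Interpret combined
  AUCs below ~0.62 as indistinguishable from chance at these
  dimensions; the package reports the estimator as defined rather
  than silently re-weighting it.
* **Selection.** Candidates are models with AUC ≥ best AUC − best
  AUC-SD; the candidate with the smallest complexity rank wins (ties
  by roster order). Ranks: LDA 1, naive Bayes 2, penalized logistic 3,
  penalized DA 4, sparse DA 5, CART 6, bagged CART 7, random forest 8 —
  plain LDA ranks simplest because it has no tuning parameter, and all
  probabilistic/linear models rank below the tree ensembles.
* **AUC and p-values.** Mann–Whitney pairwise AUC with ties counted ½;
  two-sided Mann–Whitney p-value against AUC = 0.5. Test-set reports
  use the model refit on the full training set with the training-set
  preprocessing.

## Pipeline

One YAML config; per-stage seeds derived from the master seed by
SHA-256 (all below 2³¹). Default demo conditions: 60 training and 40
test phantoms, strong coupling (`beta = 45` HU), 2 000-gene expression
with 28 sets, B = 25. Outputs are plain text (CSV/TSV/GMT, uncompressed
NIfTI when volumes are requested) plus a manifest with config hash,
seeds, census, SHA-256 file checksums and stage timings; reruns with
the same config are bit-identical.

## Known limitations

Single-lesion volumes only; no isotropic resampling by default
(features are computed on the native grid, spacing-aware); no
harmonization across scanners; the immune panel is synthetic stand-in
membership; the maximal-correlation GLCM statistic clamps its
eigenvalue to [0, 1] for numerical safety; p-values on small test sets
use the exact Mann–Whitney distribution only when sample sizes permit
(scipy's default policy).
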