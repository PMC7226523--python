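# Methods

This note documents the models and procedures implemented in `radsurv`, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Image grid and discretization

Volumes are regular 3-D grids with per-axis spacing in millimetres; the
origin is the center of voxel (0, 0, 0) (half-voxel convention).  Before
extraction, image and mask are resampled to an isotropic grid — 2 mm default
— with trilinear interpolation for the image and nearest-neighbor for the
mask; grids align by physical coordinates.  The interpolation order is a
config option (`linear`, `nearest`, `bspline`) because extraction tools vary
here and the choice measurably shifts texture values.

Gray levels are discretized with a **fixed bin width** (default 25 intensity
units) referenced to the minimum intensity inside the mask:
`level = floor((I − min)/w) + 1`.  Fixed width (rather than a fixed bin
count) keeps a given intensity contrast the same number of levels regardless
of the tumor's dynamic range, and min-referencing makes the discrete texture
features invariant to additive intensity shifts.  Each wavelet sub-band is
re-binned against its own masked minimum with the same width (configurable
via `wavelet_bin_width`); band-level first-order Entropy/Uniformity use that
re-binned histogram while the moment statistics use the raw filtered values.

## Feature panel

841 features = 105 original + 8 × 92 wavelet.

* **Shape (13)** — mesh volume, surface area, their ratio, sphericity, PCA
  axis lengths (4·√eigenvalue), elongation, flatness, maximum 3-D diameter
  and the three maximum in-plane diameters.  The surface mesh comes from
  marching cubes on the zero-padded mask after Gaussian anti-aliasing with
  σ = 0.6 voxels; without it the staircase surface of a digitized ball
  inflates area ~8% and drags sphericity to ≈ 0.92, with it a digital ball
  of radius 10 voxels measures sphericity 0.976 and volume within 1% of
  (4/3)πr³.
* **First-order (18)** — computed on continuous masked intensities; Entropy
  and Uniformity on the fixed-bin-width histogram.  Population (biased)
  moments; skewness/kurtosis of a constant region are defined as 0.
* **GLCM (23)** — symmetric co-occurrence at distance 1 over the 13 unique
  3-D directions; features evaluated per direction and averaged.
  Degenerate (single-level) regions: Correlation and MCC return the sentinel
  1, Imc1/Imc2 return 0 — sentinels, never exceptions, so a constant subroi
  cannot abort a cohort extraction.
* **GLRLM (16)** — maximal runs per direction, 13 directions averaged.
* **GLSZM (16) / GLDM (14)** — 26-connected zones; dependence = 1 + number
  of 26-neighbors within gray-level tolerance α = 0.
* **NGTDM (5)** — neighbor averages over masked 26-neighborhoods; voxels
  with no masked neighbor contribute zero difference; empty-sum guards
  return the conventional values (Coarseness capped at 10⁶).

The wavelet transform is a single-level undecimated separable filter bank
(Coiflet-1 by default, any PyWavelets name accepted), periodic boundary,
centered convolution `out[i] = Σⱼ w[j]·x[(i−j+⌊m/2⌋) mod n]` per axis; the
8 sub-bands L/H per axis stay on the input grid.  Sub-band label letters
follow axis order.

Single-voxel or otherwise degenerate regions yield NaN for a whole matrix
class, flagged, never silently dropped: a feature vector always has exactly
841 entries.

## Synthetic phantom cohorts

Each phantom is an ellipsoidal tumor (semi-axes uniform in 7–12 mm) on a
flat background, with interior intensity
`base + contrast + A_c·G(λ) + A_w·ε + lump`, where `G(λ)` is
unit-variance Gaussian-smoothed white noise with correlation length λ and
`ε` is voxel-wise white noise.  Three latent factors z ~ N(0,1) drive the
texture monotonically: λ = 3 mm·e^{0.35 z₀}, A_w = 15·e^{0.35 z₁},
A_c = 30·e^{0.35 z₂}.  The exponential link keeps every parameter positive
and gives roughly ±70% parameter range over ±2 SD of a factor — enough to
shift GLCM/NGTDM/size-zone statistics by more than a between-phantom SD.

Outcomes come from the same factors: survival times are exponential with
hazard `h₀·exp(βᵀz)` (baseline median 330 days, matching the scale of a
pancreatic-SBRT cohort), censoring is uniform on [0, c] with c solved
numerically for the target censored fraction (default 0.3); recurrence is
Bernoulli with a logistic link.  Clinical covariates are drawn from
realistic marginal frequencies (60.8% male; site 79.7% head; N1 44.6%;
T2/T3/T4 6.8/59.5/33.8%; resection 31.1%) independent of the factors, so a
clinical model is uninformative *by construction*; a
`clinical_outcome_association` switch can tilt N stage by the first factor
for sensitivity analyses.

What the phantoms do **not** emulate: CT anatomy and Hounsfield
calibration, acquisition noise spectra, segmentation variability, and
correlated clinical-imaging confounding.  Passing the synthetic studies
therefore demonstrates that the pipeline's statistics are implemented
correctly and that it can recover texture-coded signal at realistic n — not
that any particular clinical effect size is reproducible.

## Selection

Per resample (2/3 of patients without replacement; 1000 resamples at full
scale, 40 at desk scale): univariate screen with BH-FDR gate at 0.25 (a
loose gate is required — reported selected-feature FDR p-values in this
setting reach ~0.17), recursive correlation pruning at |Pearson r| > 0.8
keeping the univariately stronger member (ties broken by name for
determinism), then SFFS over the strongest 20–30 surviving candidates.

The SFFS objective is 3-fold CV of a **linear** Cox (or logistic) model —
a boosted-model objective can be substituted through
`objective_factory`, but SFFS evaluates hundreds of subsets per resample and
a linear objective keeps the stabilization loop tractable at desk scale.

The final signature is the smallest top-k-by-frequency prefix whose refit
objective is within one standard error of the best k; the refit objective is
repeated 4×3-fold CV, because a single 3-fold estimate has SEs so wide the
rule degenerates to k = 1.

Normalization: by default features are z-scored *within* each resample and
fold (leak-free).  `replication_mode=True` z-scores once over the whole
dataset and selects on all data — the historically common but leaky
workflow — and is labelled as such wherever it is reported.

## Survival and recurrence models

The boosted Cox ensemble minimizes the negative Efron partial
log-likelihood stagewise: each stage fits a depth-≤3 regression tree to the
per-sample gradient and applies a backtracking-scaled step (start at the
learning rate, halve until the loss does not increase), so training loss is
nonincreasing by construction and a stage can be rejected (scale 0) rather
than overshoot.  Hyperparameters tuned in the inner loop: number of stages
(via staged predictions of a single largest-stage fit — one fit scores every
candidate stage count), learning rate and depth if a grid is given; default
grid stages {10, 25, 50} × lr 0.1 × depth 2.  Recurrence uses sklearn
gradient boosting on logistic loss with the same staged-tuning trick.

Harrell concordance: a pair is comparable when the shorter observed time
has an event, or an event ties in time with a censoring (the censored
patient survived at least as long); two events tied in time are not
comparable; risk ties score 0.5.  AUC is the Mann–Whitney pair probability
with 0.5 for score ties; AUPRC is the step-interpolated area
Σ (R_k − R_{k−1})·P_k over descending distinct thresholds, under which a
constant scorer gets exactly the prevalence.

Nested resampling: stratified outer folds (on event/label — at n ≈ 74–150
unstratified 3-folds regularly lose all events), inner repeated CV per outer
training set, refit, score the outer test set.  Folds depend only on
(seed, repetition), so the three models are compared on identical splits.
Folds whose test set has no event or one class are flagged and excluded;
collected + flagged always equals reps × folds.  Kaplan–Meier stratification
splits at the median of per-patient risks averaged over all outer test sets
containing the patient; log-rank is computed on that pooled stratification
(per-fold curves and their pointwise average are also available).

## Clustering

Two-way UPGMA (average linkage, Euclidean) on the z-scored feature matrix;
the patient dendrogram is cut to k = 4 by default.  χ² independence tests
(no continuity correction — the contingency tables are mostly larger than
2×2) relate clusters to each clinical parameter; cells with expectation < 5
trigger a warning, zero-margin tables are skipped.

## Study designs and problem sizes

Desk-scale defaults, chosen as the package's own standard configuration:
phantoms 24³ voxels at 2 mm (tumor ≈ 400–900 voxels); recovery study 20
repeats × 150 patients, selection with 40 resamples; model comparison 50×3
outer / 10×3 inner; null control 10 independent null cohorts × 5×3 outer
folds (50×3 outer folds in total) with selection re-run leak-free inside
every outer training fold.

The null control averages over *cohorts* deliberately: at n = 120 a single
cohort's chance covariate–outcome association shifts its out-of-fold mean
metric by a few hundredths in either direction no matter how many
resampling repetitions are run, so a single-cohort null measures cohort
sampling noise rather than method calibration.

## Numerical notes

* Cox partial-likelihood code (univariate screen, multivariate Newton,
  boosting gradient) handles ties by the Efron approximation throughout and
  is validated against lifelines to ~1e-5 on coefficients and standard
  errors.  The screen fits all 841 single-covariate models in one
  vectorized damped-Newton pass (steps clipped to ±1).
* A tiny ridge (1e-9 default, 1e-4 inside CV objectives) stabilizes
  near-separable fits.
* All randomness flows from explicit integer seeds; cohort generation,
  selection and resampling are bit-reproducible given the seed.

## Known limitations

* Shape axis lengths use voxel-center PCA; for masks a few voxels across
  they under-estimate the generating ellipsoid axes.
* The wavelet boundary is periodic; tumors near the crop boundary see
  wrapped context (the crop pads 4 voxels around the mask to soften this).
* The leak-free selection mode inside nested resampling uses a reduced
  stabilization (fewer resamples) for tractability; frequencies from it are
  noisier than the full-data selection report.
* AUPRC on folds with very few positives is noisy; folds with a single
  class are excluded and counted, not imputed.
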