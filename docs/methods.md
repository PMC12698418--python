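# Methods

`collagensig` implements a complete collagen-signature workflow for
second-harmonic-generation (SHG) microscopy: quantify fibrillar-collagen
architecture in regions of interest (ROIs) with a fixed 142-feature
vocabulary, compress those features into a scalar LASSO-logistic *collagen
signature*, combine the signature with clinicopathological covariates in a
multivariate logistic model presented as a nomogram, and evaluate
discrimination, calibration and net clinical benefit. Because no real SHG
cohort ships with the package, a first-class synthetic generator produces
images and patient cohorts with known ground truth; every claim the test
suite makes is a claim about this generator's output.

## Synthetic SHG images

Fibers are angular random walks in the image plane: a starting point, an
axis angle drawn from a von Mises distribution on doubled angles
(fibers are undirected, so the axis — not a direction — is modeled;
concentration `orientation_kappa >= 0`, with 0 giving isotropy), unit-pixel
steps, and i.i.d. Gaussian turning increments with standard deviation
`curvature_sd` (radians/step; 0 gives straight fibers). Fiber length is
Gaussian (`length_mean`, `length_sd`, in um). Crosslinks are realized
generatively: `Poisson(crosslink_rate * n_fibers)` branch fibers are seeded
at random points of existing centerlines, and the seed points are recorded
as ground-truth junctions.

Rendering rasterizes each centerline at a per-fiber intensity
(`fiber_intensity_mean`/`sd`, gray units), convolves with a Gaussian whose
FWHM equals `width_mean` (um), rescales so the ridge amplitude matches the
drawn intensity, adds Gaussian background noise (`background_noise_sd`),
optionally applies Poisson speckle, and clips to 8-bit [0, 255]. The
default geometry is 512 x 512 px at 1000/512 ~ 1.953 um/px, i.e. a
1000 um x 1000 um field of view. Everything is a pure function of
(parameters, seed).

What the generator deliberately does **not** emulate: optical physics (no
point-spread function, no polarization dependence), tissue context (no
cells, no background autofluorescence structure), intensity calibration
(gray levels are arbitrary units), and fiber bundling/waviness beyond the
random-walk model. Passing tests therefore demonstrate that the
measurement and modeling chain recovers known structure from images *of
this class*; they say nothing about staining, sectioning or acquisition
artifacts in real tissue.

## Synthetic cohorts

A patient is a latent "stromal aggressiveness" `a ~ N(0,1)`, three
independent Bernoulli covariates (tumor size > 1 cm, upper-lobe location,
thyroid capsular invasion — prevalences 163/350, 92/350 and 170/350,
matching the enrolled-cohort frequencies of the emulated clinical setting),
and a binary nodal-metastasis (CLNM) outcome drawn from
`logit p = -1.7 + 1.8 a + 1.1 size + 0.95 upper + 0.8 TCI`. The intercept
puts prevalence near 41%; covariate effect sizes correspond to odds ratios
of ~3.0, ~2.6 and ~2.2, in the range reported for these factors; and the
latent-aggressiveness weight is deliberately strong so that stromal
architecture dominates the outcome, reproducing the qualitative ordering
(signature-carrying model above clinical-only model) that motivates the
method. Aggressiveness drives the imaging through a deterministic monotone
map: `crosslink_rate * exp(0.6 a)` (junctions increase),
`orientation_kappa * exp(-0.7 a)` (alignment degrades), and
`fiber_intensity_mean - 28 a` (bulk intensity falls), clipped to [40, 250].
Each patient receives 5 ROI images (the emulated sampling design) with
per-ROI seeds spawned from the cohort seed.

## Segmentation and fiber tracing

- **Mask**: global Otsu threshold on the gray histogram; connected
  components under `min_object_px = 16` removed. A constant image yields an
  empty mask plus a warning, not an error.
- **Skeleton**: topology-preserving thinning; endpoint spurs shorter than
  `spur_min_um = 4` are pruned iteratively (re-thinning between passes).
- **Fibers**: the skeleton decomposes into node-to-node/endpoint paths
  (nodes = skeleton pixels with >= 3 neighbors, 8-connectivity); at each
  junction, path ends whose continuation deviates by at most
  `merge_angle_tol = 20 deg` are greedily paired (smallest deviation first)
  and chained into single fibers, so an 'X' crossing traces as two fibers.
  Fibers shorter than `fiber_min_um = 10` are dropped.
- **Measurements**: arc length is computed on a 5-px moving-average
  smoothing of the centerline (digital 8-connected paths overestimate
  Euclidean length by up to ~8% depending on angle; smoothing removes the
  staircase bias while preserving curvature above the window).
  Straightness = endpoint chord / smoothed arc length, capped at 1. Width =
  2 x mean Euclidean-distance-transform value along the centerline.
  Orientation = principal axis of the centerline points, in [0, pi).
- **Crosslinks**: skeleton branch nodes after pruning; nodes within
  `node_merge_um = 3` are collapsed to their centroid and snapped to the
  nearest skeleton pixel. "Crosslink" here means a network junction — the
  branch-point reading used throughout the SHG fiber-analysis literature.

All thresholds are exposed in `SegmentationConfig` and recorded in run
manifests. Coordinates are 0-based (row, col), origin top-left.

## The 142 features

- **Morphological (8)**: collagen area fraction; fiber count; mean length
  (um), width (um) and straightness; crosslink density (junctions per mm^2
  of collagen area); crosslink space (mean nearest-neighbor distance among
  junctions, um); arrangement = length-weighted circular variance of
  doubled axis angles in [0, 1] (0 = perfectly aligned). Degenerate inputs
  (no fibers, < 2 crosslinks) produce zeros plus named flags.
- **Intensity (6)**: over masked pixels only — mean, variance, skewness
  (3rd standardized moment), kurtosis (4th standardized moment,
  *non-excess*, so a Gaussian scores 3), and energy / Shannon entropy (bits)
  of a 256-bin normalized histogram with the 0 log 0 = 0 convention.
- **GLCM (80)**: images quantized to 32 uniform levels over the observed
  range (a balance between co-occurrence sparsity and gray resolution);
  symmetric, normalized co-occurrence matrices at distances 1-5 px and
  angles 0/45/90/135 deg, computed over the whole ROI because co-occurrence
  over an irregular mask is ill-defined for fixed offsets. Statistics:
  contrast, correlation (0 by convention when either marginal variance
  vanishes, flagged), energy (angular second moment), and uniformity read
  as the inverse-difference moment (homogeneity) to keep it distinct from
  energy.
- **Gabor (48)**: 4 wavelengths {2, 4, 8, 16} px x 6 orientations
  {0, 30, ..., 150} deg, 1-octave bandwidth; the image is normalized to
  [0, 1] and the mean and variance of the complex response magnitude are
  recorded per filter. Convolution uses symmetric (reflected) boundary
  handling evaluated on a shared FFT grid with cached kernel transforms —
  numerically identical to direct spatial convolution and fast enough that
  a full 512 x 512 extraction (segmentation + tracing + all 142 features)
  stays under a second on one CPU.

Patient-level features are the element-wise mean of the patient's ROI
vectors (5 in the reference design; other counts are allowed with a
warning).

## Signature construction

Features are z-scored with means and *sample* SDs (ddof = 1) estimated on
training patients only; zero-variance features are dropped and listed. The
same frozen parameters transform any later cohort — they are never refit,
so the pipeline has no train/test leakage (a property asserted bit-for-bit
in the tests).

The signature is an L1-penalized logistic regression on the standardized
training matrix. The penalty grid holds 100 log-spaced values descending
from lambda_max (the smallest penalty that zeroes every coefficient,
`max |X'(y - ybar)| / n`) by a factor of 1e-4; lambda* minimizes the mean
5-fold cross-validated binomial deviance with stratified, seeded folds (the
minimum rule, not 1-SE, consistent with reporting a single optimal
lambda). Solving uses the standard pathwise strategy: per fold, a
warm-started saga solver walks the grid from large to small lambda with a
capped iteration budget per step (each solution seeds the next, so a few
passes suffice for an accurate deviance curve); the final model is refit to
convergence at lambda* on all training rows. The solver leaves the
intercept unpenalized, matching the usual coordinate-descent objective
`(1/n) nll + lambda ||w||_1`; the test suite cross-checks coefficients at a
fixed lambda against R's glmnet. A patient's signature is
`intercept + sum_i coef_i z_i` over the selected (nonzero-coefficient)
features.

Rows are patients (post ROI-averaging); ROI-level modeling is out of scope.

## Clinical modeling and nomogram

The cohort splits 6:4 (train size = round(0.6 n); simple random, seeded; no
stratification). Univariate logistic screens and the multivariate model use
maximum-likelihood logistic regression with Wald odds ratios, 95% CIs and
p-values; near-separation falls back to IRLS with a pseudo-inverse and the
affected estimates are flagged unstable rather than silently reported. The
default multivariate variable set is fixed to
{signature, location, size > 1 cm, TCI}; any other set can be passed
explicitly (the original analysis does not state whether entry was
univariate-p-gated or prespecified, so neither mode is privileged).

The nomogram is the standard points re-parameterization: each variable's
contribution `beta_v x` is mapped linearly to points so the variable with
the largest contribution span over the observed ranges spans exactly 100;
total points map back through the inverse transformation, making the
nomogram probability *identical* to the logistic probability (asserted to
1e-9). An all-zero model degenerates gracefully to `sigmoid(intercept)`.

## Evaluation

AUC is the Mann-Whitney concordance probability with half credit for ties,
computed from midranks; the C-index is its named alias for binary
outcomes. Confidence intervals are 95% percentile bootstrap with 1000
label-stratified resamples (percentile, not BCa — minimal assumptions;
degenerate single-class resamples are redrawn with a capped budget).
DeLong's test compares paired AUCs through placement values with a
two-sided normal p; the asymptotic test is slightly anticonservative below
n ~ 100–150, which is why the null-calibration study uses n = 200.
Classification metrics (sensitivity, specificity, PPV, NPV, accuracy) are
reported at Youden's J estimated on the training cohort and applied to both
cohorts (the threshold rule is configurable, including a fixed value).
Calibration curves bin by predicted-risk quantiles (deciles by default,
empty bins merged). Decision curves report
`net benefit(t) = TP/n - FP/n * t/(1-t)` against the treat-all
(`prev - (1-prev) t/(1-t)`) and treat-none (0) references for t in (0, 1)
exclusive.

## Problem sizes and determinism

End-to-end cohort runs use 128 x 128 px ROIs (250 um tiles at the default
pixel size) for the 350-patient protocol and 64 x 128 px-scale tiles for
the repeated-seed direction study, with fiber counts scaled to tile area;
single-ROI analyses default to the full 512 x 512 FOV. These tile sizes
keep a full 350 x 5-ROI protocol in the low minutes on a single CPU while
preserving every qualitative behavior tested (the per-feature monotone
responses and the integrated-vs-clinical ordering are insensitive to tile
size in our checks). A master seed spawns independent per-stage seeds
(simulation, split, LASSO folds, bootstrap) via `SeedSequence`, so stages
cannot couple through a shared stream and any run is exactly reproducible
from (config, seed).

## Known limitations

- Otsu segmentation assumes a bimodal gray histogram; very sparse or very
  dense collagen fields shift the threshold and bias area-dependent
  features (all features remain well-defined).
- Skeleton-based tracing fragments dense networks where many fibers cross
  within the merge tolerance; fiber *counts* in crowded fields are best
  read as relative, not absolute. The 90-degree-rotation equivariance of
  tracing is exact only for non-crossing fibers (greedy merge order can
  differ at junctions).
- Estimated fiber width exceeds the rendered FWHM systematically (the mask
  extends to the threshold crossing, not the half-maximum); width is
  monotone in true width, which is what the downstream models use.
- The LASSO CV deviance curve is flat near its minimum, so lambda* (and
  occasionally the selected-set margin) can shift between solver
  tolerances; selection is exactly reproducible at fixed seed and config.
- The cohort generator draws covariates independently; real
  clinicopathological covariates are correlated, so adjusted-OR behavior on
  real data may differ from the recovery simulations.
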