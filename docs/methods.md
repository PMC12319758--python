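# Methods

This note records the models, conventions and numerical choices behind
`fibertract`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Signal model and phantoms

Voxels hold a ball-and-sticks mixture: up to K = 3 anisotropic stick
compartments (volume fraction f_k, unit orientation v_k, parallel
diffusivity λ∥, zero perpendicular diffusivity) plus an isotropic ball for
the remainder.  The forward DWI signal is

    S(g, b) = S0 [ f_iso e^(−b d_iso) + Σ_k f_k e^(−b λ∥ (g·v_k)²) ].

Defaults mirror a preclinical Bruker protocol: b = 2,800 s/mm², 42
directions (electrostatic repulsion on the sphere with antipodal symmetry,
fixed seed), 4 b0 volumes, 0.25 mm isotropic voxels on a 48×48×24 grid.
Typical diffusivities: λ∥ = 1.7×10⁻³ mm²/s, ball 0.7×10⁻³ mm²/s, stick
fraction 0.7 inside a tube.  Rician noise is the magnitude of a complex
Gaussian perturbation with σ = S0/SNR, the magnitude-MRI noise model;
SNR = ∞ returns the noiseless signal bit-exactly.

Bundles are tubes: a natural/not-a-knot cubic spline through control
points, re-parameterized by arc length, swept by a fixed radius.  Voxels
within the radius get a stick along the local tangent; overlapping tubes
produce crossings (fractions renormalized if they exceed 1); more than K
overlaps is an error, not a silent truncation.

## DTI

The tensor estimator is ordinary log-linear least squares (log S regressed
on the 6 tensor elements plus intercept), with an optional WLS second pass
weighted by the squared predicted signal.  It is exact on noiseless
tensor-model data (eigenvalue recovery to ~1e-15 relative) and carries the
usual Rician bias at finite SNR (|median FA bias| < 0.05 at SNR 20 on an
FA ≈ 0.8 phantom — asserted in tests).  Negative eigenvalues are clamped to
zero and flagged, never rejected, so maps stay defined; FA of an all-zero
tensor is defined as 0.  Eigenvector signs are fixed by making the first
non-zero component of (x, y, z) positive.

Population averaging of ball-and-sticks fields is a deliberately simplified
kernel rule: per voxel, compartments across subjects are matched greedily by
angular deviation under antipodal symmetry (default matching cone 30°);
each group's orientation is the principal eigenvector of the
fraction-and-weight-weighted dyadic sum Σ w f v vᵀ; groups supported by
fewer than `min_support` (default 0.5) of the inputs are dropped.  This is
*not* a data-adaptive kernel regression with model selection and bilateral
filtering; it is the simplest faithful mixture-averaging rule, and is
labelled as such.

## Bundle-specific tractography

A bundle prior is a tract orientation map: per voxel visited by prototype
streamlines, the principal eigenvector of the segment-tangent dyadic sum
(so reversing vertex order changes nothing), plus a tracking mask (visited
voxels dilated by 1) and start/end inclusion masks (endpoint voxels dilated
by 1).  Tracking is deterministic and bidirectional from a fixed sub-voxel
seed lattice (2 per axis = 8 seeds/voxel): at initiation the reference
direction is the TOM; at continuation it is the previous step direction,
which lets streamlines curve smoothly while the TOM anchors only the start.
At each 0.1 mm step the stick compartment with fraction ≥ 0.05 closest in
angle to the reference (deviation arccos|v·r|, ties to larger fraction then
lower index) is followed; termination on mask exit, selection failure,
turning angle > 35°, or length > max.  Retained streamlines must reach the
minimum length and intersect both inclusion masks.  A bundle with fewer
than `min_count` = 10 retained streamlines is flagged missing — the
analogue of a real tractography failure.

Summaries sample each scalar map trilinearly at every vertex, average per
streamline, then across streamlines, so long streamlines do not dominate.
Bundle-mean FA is therefore a partial-volume-diluted quantity (edge
vertices mix tube and background); the test oracle compares tracked
streamlines against analytic lines with the same seeds and the same
sampling, isolating the tracking algorithm from the sampling convention.

TOM-to-subject deformation is the identity (synthetic subjects share the
grid); an affine hook exists, and full deformable registration is out of
scope.

## Synthetic cohort

The fast path draws the subjects × (bundle, metric) table directly:

* 36-bundle atlas (15 bilateral pairs + 6 midline), baselines fixed by an
  atlas seed so they are a property of the atlas, not of the cohort draw;
* between-subject variation split evenly between a subject-level intercept
  shared across bundles and independent feature noise — the intercept gives
  features the cross-subject correlation that k-NN imputation exploits;
* injury: left-hemisphere bundles (default fimbria_L, thalsub_L, intcap_L,
  cc_temp) shifted in the TBI group to a target population Cohen's d
  (|d| = 2 by default: FA down, MD/RD/AD up).  With apnea coupling c, each
  subject's shift is Δ(1 + c·z) with z its standardized log-apnea; Δ is
  calibrated analytically (Δ = d·σ/√(1 − d²wc²), w the TBI share of the
  pooled variance) so the population d still equals the target despite the
  coupling-induced variance inflation.  Unreachable combinations raise.
* apnea: log-normal, median 30 s in TBI (right-skewed, as post-impact apnea
  distributions are), small values in sham;
* sites: multiplicative factors per metric (defaults 1.0 / 1.15 / 0.9),
  counts 3 × (10 sham, 29 TBI) = 117 subjects;
* missingness: per subject × bundle Bernoulli, all four metrics of a failed
  bundle missing together; TBI rate 3× sham (0.06 vs 0.02, ≈5% overall).

The imaging route (`sample_cohort`) instead perturbs phantom bundle
parameters per subject and re-rasterizes; TBI subjects scale the injured
bundle's stick fraction by a log-normal factor (axonal loss), which is what
drives tractography failures downstream.  `make_subject_scalar_samples`
emulates each subject's voxelwise scalar-map values (log-normal tissue
distribution, 20,000 values ≈ a conservative stand-in for the ~10⁵ brain
voxels of a 250 µm rodent acquisition) for map-granularity harmonization.

What the generator does **not** emulate: registration error, EPI
distortion, motion/eddy artifacts, spatially correlated noise, bundle-shape
variability, or longitudinal within-subject correlation.  Passing tests
demonstrate the pipeline's statistical machinery under its stated model,
not robustness to those real-data effects.

## Harmonization and standardization

Per (site, metric): each subject contributes one density-normalized
histogram on common bins (128 equal-width bins over the pooled 1st–99th
percentile range); histograms are averaged with equal subject weight;
counts are smoothed with a centred moving average; the mode is the centre of
the maximum bin, ties toward the lowest centre; the scaling factor is
exactly 1/mode.  The FA support clamp to (0, 1] applies only when the data
actually lie there, preserving invariance of harmonize→standardize to a
global rescaling of all sites.

Granularity matters.  At map granularity (thousands of intensity values per
subject) the mode is sharp and a smoothing window of 21 bins estimates
site factors to well under 1% — this is the supported operating point for
site-effect removal and the one the acceptance study uses.  At
bundle-summary granularity (36 values per subject) the mode of the lumpy
atlas mixture is inherently noisy (factor error 2–5%); this route is
retained (window 5) because the end-to-end table pipeline has nothing else
to bin, and residual site effects at that level are absorbed by the sham
z-scoring and the classifier.

Standardization computes μ and σ per feature from sham rows only and
applies z = (x − μ)/σ to everyone.  Signed z-scores are the default;
absolute z-scores are available (`zmode="absolute"`), and the choice is
recorded in the output metadata.  Signed is the default because group
differences carry sign (diffusivity rises after injury) and the signed
values keep that information for effect-size work.

## Feature pipeline

Missingness is pooled over the four metric columns of a bundle (bundles
fail as a unit in tractography) and over all subjects; a bundle whose
pooled fraction *exceeds* 0.10 — strict inequality, so exactly 10% is
retained — loses all four columns.  The filter always precedes imputation.
Imputation is k-NN with k = 5: nan-aware Euclidean distances on mutually
observed features rescaled by the observed fraction, unweighted mean of the
k nearest neighbours, ties by subject order (sklearn's `KNNImputer`
convention, validated against a hand oracle).  Covariates (site, group,
apnea) are never used as imputation inputs, so labels cannot leak into
features.

## Elastic-net classification

The objective is the class-weighted binomial deviance plus the elastic-net
penalty; the intercept is unpenalized; TBI is coded 1.  Class weights are
w_c = N/(2 n_c) — "inversely proportional to the outcome frequencies" fixes
weights only up to a constant, and this normalization keeps the total
weight at N (so the weighted prevalence is exactly ½, and the null model
predicts 0.5).  The solver is coordinate descent with soft-thresholding on
the IRLS quadratic (working variance floored at 1e-5), warm-started along a
log-spaced λ path from λ_max = max_j |Σ w x_ij (y − ȳ_w)|/(Nα) down to a
ratio of 1e-4 over 100 points by default; a halving backtracking step
guarantees the true objective never increases.  Agreement with a generic
convex-optimization oracle (L-BFGS-B on the split-variable formulation) is
at machine precision on random instances; λ = 0 reproduces unpenalized
IRLS.

Nested LOOCV: the outer loop holds out one subject; class weights, the λ
path and the inner 10-fold stratified CV are all recomputed from the
training subjects only.  Inner folds are re-randomized for every outer
fold, as a fresh `cv.glmnet` call inside each training set would do.  λ is
the minimizer of mean held-out weighted deviance, ties to the larger
(sparser) λ.  Features are *not* re-standardized inside folds: the sham
z-scoring happens once upstream, and the minor information flow from sham
μ, σ is accepted and documented (a strict mode would recompute them per
fold).

Two numerical details earn their keep here.  First, coefficients below
1e-12 of the largest are zeroed after convergence: at λ = λ_max the
soft-threshold boundary can overshoot by one ULP and a 1e-16 "active"
coefficient must not masquerade as a feature.  Second, held-out
probabilities are rounded to 12 decimals before pooling: an all-null model
predicts 0.5 exactly, and sub-precision deviations — whose rounding
direction correlates with the held-out subject's class through the per-fold
class-weight recomputation — would otherwise be ranked by the AUC and can
fabricate arbitrarily extreme "performance" on label-permuted data.  Both
thresholds are far below any substantive signal.

Performance: rank (Mann–Whitney) AUC with half credit for ties; accuracy,
sensitivity and specificity at threshold 0.5 with the conventional
per-class denominators (a flag provides the divide-by-total-N variant);
bootstrap AUC CI from 1,000 subject resamples, 2.5/97.5 percentiles,
single-class replicates skipped.  The final model is one all-data fit at
the median λ across LOOCV folds; importance is |coefficient| on the
z-scored features, zeros excluded.

Replicate studies (power, permutation calibration, recovery) use a lighter
CV configuration — 15-point λ grid down to 1e-2 (the glmnet convention for
small samples), tolerance 1e-5, and for the recovery study 3 inner folds —
with problem sizes stated alongside each result.  Library defaults are
unchanged.

## Group statistics

Cohen's d uses the pooled-SD formula with the sign convention *positive ⇔
TBI below sham*, so FA loss is positive and diffusivity elevation negative.
Kruskal–Wallis is tie-corrected with chi-square p; the post hoc is pairwise
two-sided rank-sum tests with a Bonferroni multiplier equal to the number
of pairs.  Spearman p-values use the t approximation with average ranks;
the family submitted to `spearman_fdr` is adjusted by Benjamini–Hochberg
step-up.  Median-apnea stratification assigns ties to the Low group.  The
one-way ANOVA / Tukey HSD pair uses the studentized-range distribution.
The site-effect check is ordinary least squares of a feature on dummy-coded
site plus group — a deliberate fixed-effects simplification; longitudinal
random-effects modeling is out of scope.

## Known limitations

* The kernel averaging is not numerically comparable to a full
  data-adaptive kernel-regression fiber-mixture framework.
* Tracking has no probabilistic variant and no whole-tractogram filtering;
  failure behaviour is driven by the compartment-fraction threshold.
* Bundle-summary-granularity harmonization is noisy by construction (36
  values per histogram); use map granularity where intensity samples exist.
* The permutation null of class-weighted nested LOOCV is centred at 0.5
  with sd ≈ 0.07 at this study size, but is not Gaussian-tailed: in ~5–7%
  of label-permuted replicates the inner CV latches onto a feature whose
  chance correlation with the shuffled labels survives cross-validation
  (best of 36 features at N = 117 reaches r ≈ 0.25 by chance), yielding
  AUCs up to ~0.70 with a correct implementation.  Permutation inference on
  cohorts of this size should use the empirical null, not a fixed band.
* Mixed-effects longitudinal models, deformable registration, denoising
  and distortion correction are intentionally absent.
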