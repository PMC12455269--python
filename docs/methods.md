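# Methods

`amyspace` re-creates, as a tested pipeline, a cross-modal spatial-association
analysis of β-amyloid PET load: per-subject voxel-wise correlation of amyloid
SUVR maps against a transcriptome-style atlas map and against quantitative MRI
metric maps inside anatomical ROIs, followed by permutation inference on the
cohort of Fisher-transformed correlations, clinical correlation analysis, and
false-discovery-rate control. Because per-subject human imaging data of this
kind cannot be redistributed, the package ships a synthetic-cohort generator
whose statistical structure is known exactly; every pipeline stage is
validated against that ground truth or against independently coded oracles.

## The analysis model

For subject *i*, ROI *g* and target modality *m* (atlas or MRI metric), the
primary quantity is the Pearson correlation across ROI voxels

    r_igm = corr_v( SUVR_i(v), M_im(v) ),   v ∈ ROI g on the 2-mm analysis grid,

Fisher-transformed to z = atanh(r). The cohort-level question is whether the
mean |z| exceeds a medium effect size r0 = 0.3 (placed on the z scale as
atanh r0 ≈ 0.3095): with d_i = |z_i| − atanh(r0) and
T = mean(d) / (sd(d)/√n), significance comes from a one-sided sign-flip
permutation null (random negation of the d_i; exhaustive over all 2ⁿ patterns
when n ≤ 20). Validity rests on symmetry of d under the null — the standard
exchangeability condition for one-sample sign-flipping — which the calibration
suite constructs explicitly.

Clinical associations (Aim 2) are subject-level Pearson correlations of
ROI-mean SUVR with age, BMI, grip strength and fluid/crystallised cognition
(consumed as age-corrected standard scores; no internal age regression), with
two-sided permutation p-values on |r| (exhaustive for n ≤ 7). Aim 3 adds, per
MRI metric, a profile-similarity statistic: the metric's (ROI × clinical)
correlation matrix is vectorised and correlated with the amyloid matrix; its
permutation null relabels subjects and recomputes the amyloid matrix per draw.
This subject-relabelling scheme is this package's construction — the analysis
plan it mirrors only names a generic permutation engine — and is flagged as
such. Within each aim, p-values form one Storey-FDR batch; group screening
(amyloid-positive vs -negative reading) uses pooled-variance t or Pearson χ²
without continuity correction.

Permutation p-values follow the add-one convention
p = (1 + #{T* ≥ T}) / (1 + n_perm) for random draws and the exact tail
fraction for exhaustive enumeration (the identity assignment is part of the
enumeration, so p > 0 always).

## Stage-by-stage choices

**SUVR.** Voxel-wise uptake divided by the mean over a caller-supplied
reference mask (cerebellar-like). Probability masks use the
probability-weighted mean, since decimated masks arrive fractional. The
contract — reference-mask mean SUVR ≡ 1, invariance to global rescaling,
idempotence — is enforced to 1e-12.

**ROI masks.** "Probability of inclusion" is implemented as exact
volume-fraction overlap under integer-factor decimation (each coarse voxel =
fraction of its factor³ children in the mask, from integer counts), not as
interpolation; thresholding keeps voxels with probability ≥ τ (default 0.9,
inclusive, mitigating partial-volume effects). Voxel vectors use a fixed
row-major (x, y, z) ordering so voxels stay paired across modalities.

**ReHo.** Kendall's coefficient of concordance W of within-voxel time ranks
over a cubic neighbourhood, with mid-rank tie correction. The source
convention "28 neighbouring voxels" matches no standard cubic neighbourhood
(6/18/26 neighbours; 27 with the centre), so the default is the 27-voxel cube
including the centre and the neighbourhood (7/19/27) is a parameter.
Neighbourhoods truncate at volume/mask borders; all-tied neighbourhoods are
undefined and emit 0 with a logged count.

**fALFF.** Series are linearly detrended and Blackman-tapered before the
FFT; fALFF = in-band amplitude sum / total non-DC amplitude sum, with
amplitude the square root of periodogram power. The taper is a deliberate
numerical choice: in the amplitude domain, a sinusoid midway between bins
loses ≈11 % of its mass to rectangular-window sidelobes, whereas the
Blackman floor keeps in-band concentration above 0.99 while leaving the
expected spectrum of broadband signals flat (white-noise mean fALFF matches
the in-band bin fraction to < 0.01).

**wDeCe.** All pairwise Pearson correlations among mask voxels; of the
positive edges, the top ceil(sparsity · n_pos) by weight are retained
(global sparsity threshold, default 0.1; stable tie-break by edge order) and
wDeCe(v) is the sum of retained weights incident to v. Zero-variance voxels
are excluded with a logged count.

**DTI.** Log-linear weighted least squares: OLS start, then re-weighting by
squared predicted signals for a configurable number of rounds (default 2;
zero rounds is exactly OLS). The positivity constraint is eigenvalue clipping
at zero — simple and testable at desk scale, with Cholesky reparameterization
noted as the heavier alternative — and FA/MD come from the clipped spectrum.
Non-positive signals are floored at 1e-8 of the voxel's maximum before the
log. Noiseless signals invert exactly (recovery < 1e-10).

**Motion screening.** A subject fails if any frame's RMS displacement
strictly exceeds threshold_voxels × voxel_size (default 2 voxels); the
boundary passes.

**Inference numerics.** The sign-flip statistic handles the degenerate
zero-variance case explicitly (T = ±∞ by the sign of the mean; all-zero d
gives p = 1), applies a 1e-9 relative tie tolerance so patterns algebraically
equal to the observed statistic always count, and treats variance below
1e-12·Σd² as zero so identical draws give identical statistics on every code
path. Storey's π0 is estimated by a cubic polynomial smoother of π̂0(λ) on
λ = 0.05…0.95 evaluated at 0.95, capped into [1/m, 1]; batches with fewer
than 8 p-values fall back to π0 = 1 (then q-values are exactly step-up
adjusted values — this applies to the 7-ROI atlas batch).

## The synthetic cohort

Defaults are the study conditions: 35 subjects; a 64³ 1-mm high-resolution
grid decimated ×2 to a 32³ 2-mm analysis grid (1 mm rather than 0.8 mm so the
2-mm grid is an exact integer decimation); disjoint box ROIs of ~50
(entorhinal) to ~4000 (whole cortex) analysis voxels; a cerebellar-like
reference box; 488-volume TR 0.8 s BOLD; 7 b0 + 93 directions at
b = 1500/3000 s/mm² DWI; DWI-derived metrics absent for 2 subjects and CBF
for 1; clinical variables scaled to the cohort means/SDs of the emulated
study and a 24/11 negative/positive reading split.

Construction order: (1) a latent "amyloid burden" plus clinical variables
with an imposed PSD correlation matrix — forced to the *sample* moments in
exact mode (demean, sample-whiten, recolour by the Cholesky factor; requires
n_subjects > number of variables), population moments in sampling mode;
(2) per-ROI standardized atlas patterns; (3) each subject's amyloid ROI
voxels forced against the atlas pattern at the atlas-arm rho, then shifted
and scaled so ROI-mean SUVR is an affine image of the latent burden (affine
maps leave Pearson r untouched); (4) each metric map forced against that
subject's amyloid pattern at the metric's rho, plus a subject-level offset
that tracks the burden with the modality's coupling (this is what gives the
similarity arm non-degenerate clinical profiles). The forced-correlation
primitive standardizes the base, residualizes fresh noise against it exactly,
and mixes with weights ρ and √(1−ρ²), so sample correlations hit their
targets to ~1e-8.

One consequence is intrinsic to exactness: in exact mode every subject's
r equals the target, so the per-cell cross-subject variance is zero and the
sign-flip statistic sits in its degenerate ±∞ branch. Exact mode is therefore
the oracle for unit tests; sampling mode (population moments, between-subject
dispersion ≈ (1−ρ²)/√V) is the regime for calibration and end-to-end
statistics. All randomness derives from one root seed through named
SeedSequence spawn keys (per subject, per map, per analysis), making every
volume and table bit-reproducible.

What the generator does *not* emulate — anatomy, registration error, PET
partial-volume spill-in, scanner artefacts, non-Gaussian marginals — bounds
what green tests show: they certify the statistical machinery (normalization,
mask logic, metric definitions, correlation recovery, test calibration, FDR),
not robustness to real-world acquisition physics.

In the default pipeline run the association arm consumes the generator's
metric maps (which carry the forced ground truth); the raw BOLD/DWI series
feed motion screening in the pipeline and the metric-map computations in the
test suite. Deriving metric maps from the raw series inside the default run
would sever the link between the report tables and the known truth that the
end-to-end recovery checks assert.

## Problem sizes and runtime

The default end-to-end run (35 subjects, 10,000 permutations for ~130 tests)
completes in seconds on one CPU; the type-I calibration uses 1000 replicates
of 2000 permutations at n = 35; sampling-mode recovery uses 20 (ROI ×
modality) cells at 500 voxels per ROI. These sizes were chosen to make the
Monte-Carlo error small relative to the tolerances asserted (e.g. binomial
SE ≈ 0.007 for the rejection-rate band [0.03, 0.07]).

## Known limitations

- Sign-flip validity needs symmetric d under the null; skewed |z|
  distributions at the boundary can distort size, and the suite only
  certifies the symmetric construction.
- The similarity permutation scheme recomputes the amyloid profile
  complete-case over subjects, while the observed r_sim is pairwise-complete;
  with heavy missingness the two can diverge.
- The π0 smoother is a cubic polynomial, not a spline with data-driven
  smoothing; at desk-scale batch sizes (≤ 100) the difference is well below
  the q-value resolution.
- Exact mode forces *sample* moments, so downstream statistics that consume
  cross-subject variation (t statistics, similarity p-values) are degenerate
  there by design; use sampling mode for anything distributional.
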