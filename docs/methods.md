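# Methods

This note documents the models, numerical choices and limitations of
the package, stage by stage.

## Preprocessing primitives

The chain applied to a BOLD run before connectivity analysis is, in
order: steady-state discard (default k = 5 volumes), grand-mean
intensity normalization, spatial smoothing, temporal high-pass, nuisance
assembly, lesion exclusion.  The order is fixed; every threshold lives
in `RunConfig` and is serialized into outputs.

* **Grand-mean normalization** scales the run so its 4-D in-brain mean
  is 10000.  The target is an arbitrary fixed convention: any constant
  cancels in the correlation-type outputs.  Per-volume (rather than 4-D)
  scaling was the main design alternative; 4-D scaling was chosen
  because it cannot re-introduce global temporal structure.
* **Smoothing** is per-volume Gaussian convolution, per-axis sigma
  `fwhm / (2√(2 ln 2)) / voxel_dim`, reflect (symmetric) boundary
  handling.  Reflection preserves constants and the in-volume sum; the
  kernel semantics match nilearn's `smooth_img` exactly (tested).
* **High-pass** (σ = 100 s default) subtracts, at each time point, the
  value of a straight line fitted to the whole series by weighted least
  squares with Gaussian weights `exp(−Δt²/2σ²)` centred on that point;
  σ is converted to volumes through the TR.  The residual is re-centred
  on the original temporal mean, so affine-in-time series reduce exactly
  to their mean and the mean is preserved exactly.  The operator is
  linear (a t×t hat matrix), applied to all voxels by one matrix
  product.
* **Tissue series** are means over voxels at ≥ 80% tissue probability;
  all probability thresholds in the package are inclusive (≥).
  Probability maps carry an explicit `fraction`/`percent` scale tag, and
  results are invariant to the declared scale (tested).
* **Mirroring** flips images across the mid-sagittal plane, identified
  from the affine's orientation codes, so all lesions sit on one
  configured hemisphere.  It is applied once at ingest, images only
  (clinical scores are never side-flipped), and the flip is recorded.

## Lesion load

`wcst_ll` sums (1/10)·I(n)·voxel-volume over lesion∩tract voxels with
I(n) in percent.  The per-voxel weight is the probability itself
("linear"); a "squared" mode (I²/100, the reading in which the
probability enters twice) is available as configuration.  Voxels with
tract probability exactly 0 never count toward n_max.  Both the
weighted value and the raw overlap volume (n_max × voxel volume) are
reported, since published lesion-load tables do not always state which
of the two they print.

## Seed GLM

Design matrix: intercept, seed mean series, nine nuisance columns (CSF,
WM, global signal, six motion parameters).  OLS per in-mask voxel; the
seed coefficient's t(df) statistic maps to Z by matching upper-tail
probabilities through log survival functions, which stays accurate for
|t| > 8; Z is capped at ±38.  Residual variance has a relative floor
(1e-24 of the mean squared signal) so perfectly fitted voxels (constant
or exactly collinear series) yield capped or zero statistics instead of
0/0.  Adding any linear combination of nuisance columns to every voxel
leaves the seed Z map unchanged to < 1e-6 (tested as an invariant).

## Smoothness estimation

Residual series are normalized to unit sum of squares per voxel; per
axis, the mean squared spatial difference λ of the normalized residuals
gives the lag-one autocorrelation ρ = 1 − λ/2, inverted through a
Gaussian autocorrelation model, FWHM = √(−2 ln 2 / ln ρ).  The FWHM is
floored at 1 voxel — the resolution limit of the grid — which is also
what the estimator reports for white noise.  RESELs = mask voxels /
Π FWHM.  On fields smoothed with a known 2-voxel-FWHM kernel the
estimator recovers 2.0 within a few percent.

## GRF cluster-extent inference

Clusters are 26-connected components of {Z > z_thr} (strict at the
subject level, inclusive Z ≥ z_thr at the group level, following the
conventional statement of the two thresholds).  The corrected p for a
cluster of k voxels is the classical two-step cluster-extent result

    p_FWE(k) = 1 − exp(−E[m] · P(n ≥ k)),
    P(n ≥ k) = exp(−β k^{2/3}),  β = [Γ(5/2) E[m_cont] / E[N]]^{2/3},

with E[N] the expected suprathreshold voxel count and E[m_cont] the
continuum expected cluster count from the 3-D EC density.  Two
finite-sample refinements are applied, both adopted because Monte-Carlo
calibration of the continuum-only formula showed it conservative at
small smoothness (FWHM ≈ 2 voxels):

1. **Lattice cluster count.**  The number of *detected* clusters uses
   the expected Euler characteristic of the excursion set's closed
   voxel-cube complex on the sampling lattice (cells present when any
   incident voxel exceeds z), computed from the Gaussian
   autocorrelation implied by the estimated FWHM.  The orthant
   probabilities involved (2-, 4- and 8-voxel blocks) are evaluated by
   seeded scrambled-Sobol quasi Monte Carlo, deterministic and cached.
   At FWHM 2 voxels and z = 2.3 on a 32³ grid the continuum density
   predicts ≈146 clusters while ≈105 are observed; the lattice EC
   predicts ≈106.
2. **Boundary truncation.**  Clusters centred within one cluster radius
   of the mask surface lose on average 18.75% of their volume (mean
   visible fraction of a sphere against a planar boundary), so an
   observed extent k is referred to the distribution at k / t(k), with
   t(k) computed from the mask's exposed-face count.

With both refinements the empirical family-wise error of the null
calibration (500 smooth Gaussian fields, 32³, FWHM 2, z > 2.3,
α = 0.05) sits near the nominal 0.05; without them it is ≈0.02.
Mask-boundary corrections to the EC itself (surface resel terms) are
not applied.

The group model is a one-sample OLS GLM (t = mean/(sd/√n), df = n − 1)
across subject Z maps with an sd floor for degenerate voxels — a
deliberate, provenance-tagged stand-in for Bayesian mixed-effects
estimation, whose exact behaviour is tool-internal and not publicly
specified.  Between-subject residual maps feed the smoothness estimate;
when residuals vanish (identical inputs) a 1-voxel fallback smoothness
is used.

## Laterality

LI consumes the GRF-surviving mask by default; a voxelwise-threshold
variant (`li_input="voxelwise"`) is provided because published
descriptions do not always state which map feeds the counts.  ROIs are
the bilateral seed-generation masks; masks that cross the midline must
be split at the mid-sagittal plane first (`split_mask_by_midline`),
which guarantees the disjointness the formula presumes.  The index is
exactly antisymmetric in its ROI arguments and invariant to changes of
the map outside both ROIs.

## Synthetic phantoms

The generator plants known structure so every downstream stage has an
oracle:

* **Anatomy** (32×32×24 grid, 3 mm voxels): ellipsoidal brain with CSF
  shell, WM core and GM ribbon; bilateral S1/M1-like Gaussian-bump ROIs
  (exact mirror images, peak 1) plus occipital/parietal satellites; a
  Gaussian-tube tract descending through one hemisphere.  Grid and run
  length (150 volumes, TR 2.3 s) keep a full subject run under a
  second on one CPU while leaving ≥100 residual df in the GLM.
* **BOLD** is a shared-latent-factor model: per homotopic pair a shared
  factor with planted left/right correlation c, a hemisphere factor
  tying same-side ROIs, a GM-weighted global factor, CSF/WM-specific
  fluctuations, a sinusoidal drift, a linear admixture of the six
  motion parameters (a random walk), and white noise, all on a baseline
  of 1000.  Because the model is linear in unit-variance latents with a
  known correlation matrix, the correlation of any two ROI-mean series
  has a closed form (`planted_pair_correlation`) used as the test
  oracle.  Coupling values are the study conditions for the asymmetry
  tests: symmetric phantoms use c = 0.7–0.8, the planted-asymmetry grid
  is c ∈ {0.8, 0.5, 0.2, 0.0}.
* **Lesions** are spheres clipped to the brain; a bisection on the
  radius drives the lesion∩tract fraction to a target within ±0.05.
* **Cohorts** draw lesion volumes uniform on [500, 40000] mm³ and LI
  uniform on [−0.2, 1]; outcomes are linear in (lesion volume, LI) plus
  Gaussian noise, clipped to the clinical ranges (NIHSS ≥ 0, Chedoke
  1–7).  Scores are kept continuous rather than integer-rounded so that
  coefficient and ΔR² recovery are exact in expectation; with
  independent predictors the population ΔR² of the second block is
  β_LI²·Var(LI) / Var(outcome), available as `CohortSpec.analytic_r2`.

What the phantoms do **not** emulate: hemodynamic response shape,
cardiac/respiratory noise spectra, scanner drift families beyond a
sinusoid, registration error, through-plane motion artifacts, or
non-Gaussian autocorrelation of real BOLD noise.  Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to every property of real data — in
particular, GRF cluster p-values are known to be optimistic on real
fMRI autocorrelation structures at low cluster-forming thresholds.

## Worked-example cohort

The bundled eight-patient table was transcribed from a published
patient-characteristics table whose text rendering had lost the numeric
cell separators; the transcription is the most plausible consistent
reading (see the docstring in `hemiconn.datasets`) and reproduces the
published correlation structure in sign and approximate magnitude,
though not to the printed third decimal.  The published group-level
connectivity maps and regression values cannot be recomputed from
printed data at all (raw fMRI and per-subject LI values are not
published); the direction-of-effect phantom tests and the
regression-recovery properties stand in for them.

## Degenerate inputs and tie-breaks

Grid mismatches are errors, never implicit resampling.  Empty seeds or
tissue masks after thresholding/exclusion are errors carrying the stage
name.  Cluster tables sort by extent descending; peak coordinates take
the first maximal voxel in array order.  All generators are pure
functions of (spec, seed); reruns are bit-identical.
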