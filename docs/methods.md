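# Methods

This note documents the models, conventions and numerical choices behind
`dtialps`, in the order data flows through the pipeline.

## Forward DWI model and phantom

Each phantom voxel carries a symmetric positive-definite diffusion tensor
`D` (6 unique elements, mm²/s). The noiseless signal for a gradient-table
entry with b-value `b` and unit direction `g` is the single-tensor
mono-exponential model

    S = S0 · exp(−b · gᵀ D g).

Noise models: `gaussian` adds N(0, σ) to the signal; `rician` takes the
magnitude of the complex signal perturbed by independent N(0, σ) on both
channels. In both cases σ = S0 / SNR, with SNR defined against the b = 0
signal. The default SNR is 30, a typical magnitude-MRI operating point; the
default noise model is Rician, the physically correct magnitude-image
distribution.

The default acquisition mirrors a routine clinical DTI protocol: one b = 0
volume plus 20 encoding directions at b = 1000 s/mm². Because vendor
direction tables are not public, directions are generated deterministically:
a golden-angle (Fibonacci) hemisphere seeding refined by 200 iterations of
electrostatic repulsion over antipodally symmetrized charges. For 20
directions the minimum pairwise separation is ≈ 29°, and the same
`n_directions` always yields bit-identical tables.

The default phantom is a 40 × 40 × 20 grid of 2 mm voxels holding two
mirror-image hemisphere blocks separated by a 4-voxel central "ventricle"
gap. Each hemisphere contains a projection-fiber slab (diffusion dominant
along z) against the gap and an association-fiber slab (dominant along y)
lateral to it, over an isotropic background (0.8 × 10⁻³ mm²/s). The slab
tensors are parameterized so the analytic ALPS index is exactly a requested
target: the denominator diffusivities are fixed (Dyy_proj = 0.4 × 10⁻³,
Dzz_assoc = 0.6 × 10⁻³) and both slabs' Dxx is set to `target × 0.5 × 10⁻³`.
This phantom reproduces the ROI geometry of the ALPS protocol; it makes no
attempt to model eddy currents, motion, susceptibility distortion or
partial-volume effects, so passing phantom tests demonstrates correctness of
the estimation chain, not robustness to acquisition artifacts.

## Tensor fitting

Per voxel the log-linear system `ln S_i = ln S0 − b_i g_iᵀ D g_i` is solved
over the 7-parameter design (ln S0 + 6 tensor elements). `ols` is a single
unweighted solve; `wls` (the default) adds one refinement pass weighted by
the squared predicted signal, the standard correction for the
heteroscedasticity introduced by the log transform. Both are fully
vectorized over voxels via batched normal equations.

Degenerate measurements are handled deterministically: non-positive
intensities on diffusion-weighted entries are dropped (weight zero) for that
voxel; a voxel is marked invalid — never a crash — when fewer than 7 usable
entries or no positive b = 0 entry remain. Negative fitted eigenvalues are
*retained* in the stored tensor and clamped to zero only inside FA/MD
computation, because the ALPS index consumes the raw diagonal elements and
silently altering them would bias it.

Scalar maps follow the usual definitions: FA = √(3/2)·√Σ(λᵢ−λ̄)²/√Σλᵢ²
(0 when all eigenvalues are 0), MD = λ̄, and the directionally encoded
color map is FA · (|e1x|, |e1y|, |e1z|) with e1 the principal eigenvector.
The Dxx/Dyy/Dzz maps are tensor diagonal elements, not eigenvalues.

Under noise, the FA of a truly isotropic voxel has a positive floor driven
by eigenvalue-dispersion noise; for this 21-measurement protocol the median
floor is ≈ 2.5/SNR (measured: 0.084 at SNR 30, 0.050 at SNR 50). Tests of
"FA ≈ 0" on noisy isotropic data must budget for this floor; it is a
property of the estimator, not a bug.

## ROIs and the ALPS index

ROIs are in-plane circular disks on one axial slice (the
lateral-ventricle-body level), default diameter 5 mm. A voxel belongs to a
disk iff its *center* lies within the radius — a deterministic,
orientation-independent rule (e.g. 21 voxels for a 5 mm disk on 1 mm voxels
centered on a voxel center). ROI placement on real anatomy is config-driven
(explicit per-subject `RoiSpec` lists in YAML/JSON); automatic placement
exists only for the phantom, whose slab centers are known. Single-placement
semantics are used throughout (no multi-reader averaging). An optional
exclusion mask (e.g. lesions) removes voxels from a ROI; partial exclusion
shrinks the mean with a logged retained-voxel count, full exclusion is an
error.

Per hemisphere, ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj,
Dzz_assoc). The **total-cerebral** index is defined here as the arithmetic
mean of the two hemispheric indices — the simplest symmetric pooling. An
index computed over pooled left+right ROI means would differ slightly;
consumers comparing against other implementations should check which
convention those use.

Hemisphere labels never live in storage: results are kept left/right, and
stimulated/non-stimulated labels attach only through the explicit mapping
(HF → stimulated = infarcted side; LF → stimulated = opposite side), which
prevents silent label swaps between treatment arms.

## Cohort generator

`generate_cohort` emulates a 35-subject two-arm trial (17 HF / 18 LF by
default). Per group it draws:

- covariates — age, BMI, lymphocytes: normal with the group means/SDs;
  sex: fixed male count = round(fraction × n); days since onset: lognormal
  (right-skewed, parameterized by median and log-SD); follow-up interval:
  normal (14 ± 3 d HF, 13 ± 3 d LF), rounded, floored at 7 d;
- hemispheric baseline ALPS: bivariate normal with inter-hemisphere
  correlation 0.5 (a plausible bilateral coupling; not separately
  identifiable from group summaries); total = hemisphere mean;
- per-hemisphere change rates (% per day) from the group effect
  distributions, with follow-up ALPS placed by inverting the change-rate
  definition, FU = BL · (1 + rate/100 · days) — so recomputing the rate
  from the emitted table returns the drawn values to machine precision;
- clinical scales as rounded, range-clipped draws (the scales are ordinal
  and bounded); baselines approximate the published group medians/IQRs or
  means/SDs, improvements are positive for NIHSS (sign-flipped), Brunnstrom,
  FMA, WMFT, ADL and QOL and null for MAS, modified Ashworth and SWMT.

A Gaussian copula couples the latent normals of (stimulated rate,
non-stimulated rate, ΔWMFT, ΔFMA) with correlation matrix built from
`rate_corr` (0.5), `rho_wmft` (−0.42, non-stimulated rate ↔ ΔWMFT) and
`rho_fma` (0.35, stimulated rate ↔ ΔFMA); infeasible combinations are
rejected at spec validation by a Cholesky check that names the offending
parameters.

`empirical=True` affinely standardizes the drawn ALPS baselines and change
rates so their per-group *sample* mean/SD equal the parameters exactly
(the `mvrnorm(empirical=TRUE)` idiom; affine maps preserve the copula
correlations). This mode turns published group-summary tables into a
concrete cohort whose summary-determined statistics (group means, pooled
two-sample t on hemispheric change rates) are reproduced exactly, which is
how the package replicates printed trial statistics in the absence of the
underlying raw data. Quantities that depend on the unpublished joint
distribution — paired t, Spearman correlations, adjusted-regression
coefficients, anything involving the *derived* total-cerebral rate — are
reproduced only in expectation. Two consequences worth knowing:

- the sample Spearman correlation at n = 17 is attenuated relative to the
  latent copula correlation: under a bivariate-normal copula its expectation
  is (6/(π(n+1)))(asin ρ + (n−2) asin(ρ/2)) ≈ 0.91 ρ, and ordinal
  rounding/clipping of the clinical scales shrinks it a few points further;
- the within-arm paired t on BL vs FU implied by marginal rate moments need
  not equal a published value computed from raw data (the implied LF
  total-cerebral paired t is ≈ −1.0 under these parameters regardless of
  seed).

For calibration experiments leave `empirical=False` (the default): genuine
sampling variability is then the point, and the generator's fixed-seed
output is bit-identical across runs.

## Statistical conventions

- Orientations are fixed: paired tests report mean(BL − FU); group
  contrasts report HF − LF. Signs are therefore reproducible.
- Two-sample t is Student (pooled variance) by default; Welch sits behind
  `pooled=False`.
- The Wilcoxon signed-rank test drops zero differences, averages tied
  ranks, and uses the exact tie-aware null distribution for effective
  n ≤ 25, built from the generating function ∏(1 + x^{2rᵢ})/2ⁿ by
  polynomial convolution (doubling makes tied half-ranks integral); beyond
  that, the tie-corrected normal approximation. This is implemented
  in-package because the stock exact methods refuse ties.
- Mann-Whitney U reports the tie-corrected standardized Z alongside U;
  exact p for small untied samples.
- Spearman p-values use the t approximation with df = n − 2.
- The normality gate is Shapiro-Wilk at α = 0.05 per group; a baseline
  contrast uses Student t only when both groups pass.
- Adjusted regression is OLS of the outcome on a group indicator (HF = 1)
  plus age, sex (male = 1), BMI and onset days, reporting the group β with
  its 95% CI; rank-deficient designs are rejected naming the collinear
  columns.
- FDR families are explicit and logged in every report: the three regional
  change-rate contrasts form one family; each correlation row (one region ×
  nine scales) forms its own family. BH adjustment is monotone in the
  sorted order but not idempotent in general; only the standard single
  application is performed.
- Missing values are handled by listwise deletion per analysis block with a
  logged dropped-row count.

## Problem sizes and tolerances

The test suite and the acceptance script run on: the 40 × 40 × 20 phantom
(noiseless recovery asserted to 1e−6 on the ALPS index and 1e−8 relative on
tensor elements; 5% under Rician SNR 30), 100-tensor fit oracles, 50-cohort
ensembles for sampling-sensitive statistics, 2,000 null cohorts for type-I
calibration (±3 binomial SE around 5%) and 500–1,000 cohorts for
effect-size recovery (±4 SE of the mean). These sizes keep the full run in
tens of seconds while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

- The phantom is artifact-free by construction; no claim is made about
  motion/eddy/distortion robustness, and no preprocessing is implemented.
- No numerical parity with any specific scanner or FSL fit flavor is
  claimed; the fit is a standard log-linear OLS/WLS.
- The ALPS implementation covers the classic axial-ROI protocol only — no
  along-vein reorientation variants, no atlas registration, no automatic
  ventricle-level detection.
- The cohort generator reproduces group summaries and targeted pairwise
  correlations, not the full unpublished joint distribution of a real
  trial; statistics driven by that joint structure are matched in
  expectation only.
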