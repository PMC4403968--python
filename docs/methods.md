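# Methods

## Signal models

**Mono-exponential (ADC).** S(b) = S₀ · exp(−b·ADC). Fitted by ordinary
least squares on ln S versus b with a free intercept, so the b = 0
amplitude is estimated, not pinned. Repeated b-values are averaged
before fitting; with exactly two distinct b-values this reduces to the
closed form ADC = ln(S₀/S_b)/b. Non-positive signals make the log fit
impossible; such voxels are flagged invalid (NaN in maps) rather than
raising.

**IVIM bi-exponential.** S(b) = S₀ · (f·exp(−b·D*) + (1−f)·exp(−b·D)),
with perfusion fraction f ∈ [0, 1], pseudo-diffusion D* and tissue
diffusivity D ≤ D*. Fitted by the segmented (stepwise) method standard
in the clinical literature:

1. D and the tissue amplitude from the log-linear fit restricted to
   b ≥ 300 s mm⁻² (`b_threshold`, configurable), where the perfusion
   term has essentially decayed;
2. f and D* by Nelder–Mead on the full curve with D fixed, using a
   logistic reparameterisation to enforce f ∈ [0, 1] and
   D* ∈ [D, 1 mm² s⁻¹].

The single-pass step 1 carries a small positive D bias (the perfusion
term is not exactly zero at b ≥ 300): below 3 % over the tissue-typical
grid f ≤ 0.15, D* ≥ 10⁻² mm² s⁻¹. The optional `refine` parameter
iterates the two steps — subtracting the current perfusion estimate
from the high-b signals before refitting D — which converges to the
generating parameters on noiseless data (≤ 10⁻⁶ relative error on the
acceptance grid, typically ≤ 10⁻¹⁰). Default is one pass (the
literature-standard estimator); analyses that need exact noiseless
round trips use `refine`.

**Diffusion tensor.** ln S = ln S₀ − b·gᵀDg, fitted by log-linear least
squares with the 7-parameter design (intercept + 6 unique tensor
elements). MD is the eigenvalue mean; FA the usual normalised
eigenvalue dispersion, with negative eigenvalues clamped to zero before
FA (clamping is flagged in the fit log) and FA capped at 1. At least
six non-collinear directions are required; rank-deficient schemes raise
a fit error.

## Noise model

Rician: S_noisy = √((S + n₁)² + n₂²), with n₁, n₂ ~ N(0, σ²). σ = 0 is
an exact identity. At zero signal the expectation is σ·√(π/2) — the
noise floor that inflates apparent perfusion fractions: with true
f = 0, the mean fitted f rises monotonically with σ (acceptance
criterion 5 and `analysis/05_noise_floor.py`).

## Phantom

Ice-water phantom: five water tubes (D = 1.099 × 10⁻³ mm² s⁻¹ at 0 °C)
on a ring around one central sucrose tube (default
0.5 × 10⁻³ mm² s⁻¹), cylinders along the slice axis in a 48×48×4
volume, S₀ = 1000, zero background. Water is perfusion-free, so its
IVIM signal is mono-exponential. ROI means are taken over the water
labels after one 6-connectivity erosion (when the tube radius permits)
to avoid edge partial-volume voxels.

## Study generator

Measurements follow y = μ(metric, region) + scanner_i + volunteer_j + ε,
with fixed scanner offsets (drawn once per design from N(0, σ_scanner)),
random volunteer effects N(0, σ_vol) and residuals N(0, σ_intra). The
replica design has 8 scanners (4 at 1.5 T, 4 at 3 T), 9 volunteers,
52 volunteer–scanner pairs and 13 repeat sessions (65 sessions). Default
effect sizes (printed 10⁻³ scale) per metric:

| metric | grand mean GM/WM | σ_scanner | σ_vol  | σ_intra |
|--------|------------------|-----------|--------|---------|
| ADC    | 0.83 / 0.70      | 0.020     | 0.020  | 0.015   |
| D      | 0.75 / 0.65      | 0.022     | 0.015  | 0.012   |
| f      | 0.10 / 0.08      | 0.020     | 0.003  | 0.008   |
| MD     | 0.85 / 0.70      | 0.015     | 0.012  | 0.015   |
| FA     | 0.17 / 0.42      | 0.006     | 0.012  | 0.011   |

These are package defaults chosen to be of the order of the published
variance components; they are all overridable. All randomness descends
from one explicit seed through `numpy.random.SeedSequence` spawning, so
every output is reproducible and no global RNG state is touched.

## Variance components, CV and ICC

The mixed model y = μ + scanner (fixed) + volunteer (random) + ε is fit
by REML (statsmodels `MixedLM`, Powell optimiser with tight tolerances
xtol = 10⁻¹², ftol = 10⁻¹⁴; L-BFGS fallback). On balanced designs this
coincides with the closed-form balanced-ANOVA method-of-moments
estimators to ≤ 10⁻⁶ relative (tested). σ_inter is the sample SD
(ddof = 1) of the estimated scanner means; μ their unweighted mean.
CV = 100·σ/μ, ICC_inter = σ_inter²/(σ_inter² + σ_intra²) and
ICC_intra = 1 − ICC_inter. The minimum detectable change is reported as
2 × CV_inter. Subgroup reports repeat the analysis within each field
strength; a subgroup with fewer than two scanners is flagged, not
fatal.

**Boundary (NE) rule.** A REML variance component whose truth is zero
collapses to the boundary in roughly half of replicates. The volunteer
component is reported NE (not estimable) when
σ_vol/σ_intra < 10⁻³. This threshold was chosen empirically: boundary
fits resolve to ratios ≤ 2 × 10⁻⁴ while genuinely positive components
give ratios ≥ 0.07 in all observed simulations, so the rule separates
the two regimes with orders of magnitude of margin (lme4's singularity
check uses 10⁻⁴ on the same ratio). A noiseless degenerate design
(zero residual after scanner means) bypasses the optimiser entirely and
uses the exact closed form.

## ROI handling

Probability maps are thresholded with a strict `>` comparison (default
0.95). Erosion uses `scipy.ndimage.binary_erosion` with 6- or
26-connectivity structuring elements. ROI means ignore NaN sentinels
(failed fits) and report the contributing voxel count; empty ROIs are
logged and omitted from the measurement table rather than raising.

## Limitations

* The segmented IVIM fit is a per-voxel estimator; no spatial
  regularisation or Bayesian shrinkage is implemented, so f and D* are
  noisy at clinical SNR (visible in `results/noise_floor.csv`).
* Only the balanced-ANOVA oracle is exact; on unbalanced designs (such
  as the replica study) the REML estimates are the reference and are
  validated indirectly via recovery simulations.
* The default single-pass IVIM fit retains the documented ≤ 3 % D bias;
  use `refine` when unbiased noiseless recovery matters.
* The phantom simulator models ideal cylinders without susceptibility,
  eddy-current or motion artefacts; scanner differences enter only as
  diffusivity offsets and noise levels.
* ICC values are reported for the scanner/residual split only; the
  volunteer component enters the CVs but not an ICC.
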