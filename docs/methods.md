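# Methods

## Signal model and estimator

The package models the diffusion-weighted magnitude signal along direction
**n** at b-value *b* (s/mm²) as

ln S(b,n) = ln S0 − b·D_app(n) + (1/6)·b²·D_app(n)²·K_app(n),

where D_app(n) = nᵀDn projects the symmetric second-order diffusion tensor
D (mm²/s) and K_app(n) = (MD²/D_app(n)²)·Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ projects the
fully symmetric fourth-order kurtosis tensor W (dimensionless), with
MD = tr(D)/3. W has 15 unique elements (multiplicities 1/4/6/12 by index
pattern); D has 6. Substituting V ≡ MD²·W makes the model linear in the 22
unknowns (ln S0, D, V).

**Estimator.** Weighted linear least squares on ln S: an unweighted solve
initializes the predictions, one reweighting pass with weights equal to the
squared predicted signal corrects the heteroscedasticity induced by the log
transform of (approximately) constant-variance magnitude noise. The
weighted pass is solved by batched QR on the √weight-scaled design rather
than by normal equations, which would square the condition number. The
design is internally rescaled (b in ms/µm², D in µm²/ms) so all columns are
O(1); without this, recovery error saturates near 1e-8 relative instead of
1e-13. A deliberately linear, deterministic estimator was chosen over
nonlinear fitting: it is the standard reference estimator, has no
initialization or convergence failure modes, and makes the round-trip
tests exact.

Degenerate voxels are flagged (bit field), never raised: voxels with any
non-positive or non-finite sample are excluded from the fit entirely
(log-domain fitting does not admit flooring them), voxels with
non-positive mean diffusivity or eigenvalues are marked invalid, and a
singular weighted system falls back to the unweighted solution.

## Scalar maps

With R the eigenvector matrix of D (columns ordered by descending
eigenvalue λ₁ ≥ λ₂ ≥ λ₃), the kurtosis tensor in the eigenframe is
Ŵᵢⱼₖₗ = Σ R_aᵢR_bⱼR_cₖR_dₗ W_abcd, and the eigen-kurtoses are
K̂ᵢ = (MD²/λᵢ²)·Ŵᵢᵢᵢᵢ. Then

* axial kurtosis K∥ = K̂₁ (along the principal diffusion direction),
* radial kurtosis K⊥ = (K̂₂ + K̂₃)/2, the arithmetic mean of the two
  non-principal eigen-kurtoses (not the analytic perpendicular-plane
  integral — the simpler definition matches the convention of
  vendor-toolbox-era gray-matter studies),
* MK = mean of K_app over a direction set. The default set is the
  acquired nonzero-b directions (the convention of scanner toolboxes); a
  deterministic 321-point Fibonacci half-sphere is available
  (`mk_directions="sphere321"`). On random physiological tensors the two
  choices differ by well under 0.05 in mean absolute terms (tested).

Exact eigenvalue ties make the eigenframe, hence K∥/K⊥, ill-defined; the
deterministic LAPACK eigensolver's ordering is accepted as the tie-break
convention. Ties have measure zero under noise.

Metrics are clipped to [0, 10] by default (configurable); clipped or
negative-kurtosis voxels are flagged, not discarded, to preserve
auditability.

## Synthetic data

The generator emulates the study conditions rather than real anatomy:

* **Acquisition**: b = 0, 1000, 2000 s/mm², 25 directions per nonzero
  shell (51 volumes). Direction sets come from electrostatic repulsion
  with antipodal symmetry (L-BFGS on the Coulomb energy, seeded and
  deterministic), since the scanner's native vectors are not published.
* **Phantom**: 24³ grid at 2 mm isotropic (the analysis grid of the
  modelled study). Two tissue classes: a "gray-matter-like" ball with
  λ = (1.2, 1.0, 0.9)·10⁻³ mm²/s and isotropic kurtosis
  (Wᵢᵢᵢᵢ = 0.9, Wᵢᵢⱼⱼ = 0.3), giving MK ≈ 0.9; and an embedded 5³-voxel
  "lesion" with identical baseline tensors. These are physiological
  ballpark values for cortical tissue at 3 T, chosen once as generator
  defaults.
* **Noise**: Rician, as appropriate for magnitude MRI —
  S = |(S₀ₜᵣᵤₑ + ε₁, ε₂)| with ε ~ N(0, s0/SNR). SNR is defined at b = 0;
  the default 46 is the top of the 26–46 range stated for the modelled
  acquisition. Empirical b0 noise SD matches s0/SNR within a few percent
  over ≥10⁴ voxels (tested at 46 and 26).
* **Group effect**: the patient group's W is multiplied by
  `kurtosis_scale` ∈ (0, 1] inside the lesion, scaling MK, K∥ and K⊥ by
  exactly that factor (kurtosis deficits in patients, the direction of the
  modelled finding).
* **Clinical scores**: normal draws per scale from the published group
  means/SDs, rounded to integers and clipped to each instrument's valid
  range (they are integer instruments). Clipping slightly biases means of
  scales whose group mean sits within ~1.5 SD of a bound (e.g. control
  CIAS, +0.5 at the 26-point floor); scales far from their bounds
  reproduce their means within 1%. An optional linkage parameter draws
  patient CIAS z-scores as r·z_kurtosis + √(1−r²)·ε so the population
  correlation with a per-subject regional-kurtosis deviation equals r.
* The published per-subject score table ships verbatim as a CSV fixture.
  Two known discrepancies in the source are preserved rather than
  repaired: the patient-group SDS mean recomputed from the per-subject
  rows (54.33) differs from the printed summary (54.72), so that one cell
  is never asserted; and the printed sex p-value (0.06 for 15/3 vs 18/3)
  matches neither the plain nor the continuity-corrected chi-square, so
  both variants are offered and neither value is asserted.

What the generator does **not** emulate: anatomy, spatial normalization
(all subjects share the grid by construction), eddy currents,
susceptibility distortion, motion, partial volume, or spatially varying
noise. Passing tests therefore validate the estimator, the statistics and
their calibration — not robustness to real-scanner artifacts.

## Spatial operations

Gray-matter masks are binarized at probability **strictly greater than**
the threshold (default 0.5). Smoothing uses FWHM = σ·√(8 ln 2) per axis
(anisotropic voxels handled per-axis), zero-padded for whole-volume use
and mask-renormalized (smoothed masked volume ÷ smoothed mask) for
statistics inputs, which removes edge attenuation on small phantoms.
Smoothing precedes masking in the pipeline (the order is unstated in the
modelled workflow; it is configurable). Grid/affine mismatches raise
instead of resampling — silent resampling hides registration errors, and
phantoms never need it.

## Group statistics and cluster correction

Voxelwise pooled-variance two-sample t (sign convention patients −
controls), two-tailed p on n₁+n₂−2 df; zero-variance voxels are dropped
from the mask with a count. The cluster-forming threshold is two-tailed
(default p < 0.001) with sign retained; positive and negative
suprathreshold sets are clustered separately (a cluster cannot mix signs).

The extent threshold k_min is derived by Monte-Carlo simulation: Gaussian
white-noise fields on the mask's grid, smoothed to the assumed field
smoothness, standardized within the mask, thresholded two-tailed at the
forming p, largest cluster recorded per iteration (default 1000);
k_min is the smallest extent whose exceedance fraction is ≤ the corrected
level (default 0.05). Design choices:

* **Connectivity** defaults to 18 (configurable 6/26) — the common
  SPM-world convention; the published 13-voxel threshold depends on this
  unstated choice, so it is exposed.
* **Field smoothness** is taken as the pipeline's applied FWHM (6 mm)
  rather than estimated from residuals: the phantom's true smoothness is
  known. Residual-based estimation is a noted extension.
* The published k_min = 13 is treated as dataset-dependent output, never
  hard-coded; on the default phantom mask the same procedure yields
  k_min ≈ 10–11.

Calibration is verified two ways: (i) 500 fresh null two-group datasets of
smoothed Gaussian subject maps run through the identical t/forming/extent
pipeline give a family-wise error inside the 95% binomial band around
0.05; (ii) full null DWI cohorts (no effect, independent Rician noise,
complete fit-smooth-test pipeline) survive at a rate consistent with 0.05.

## ROI correlation

Per-subject unweighted means of a metric over a cluster-derived ROI,
correlated with the severity score by sample Pearson r with the exact
two-tailed t-transform p (t = r·√((n−2)/(1−r²)), n−2 df). Correlations are
computed within the patient group only (n = 18) and no multiplicity
adjustment is applied across ROIs, mirroring the modelled analysis; the
output table records n so readers can judge power.

## Clinical table

Group means with sample SD (n−1), equal-variance two-sample t (the modelled
study verified homogeneity of variance; Welch available behind a flag),
Pearson chi-square for sex (Yates correction behind a flag). Degenerate
cases (zero variance in both groups) yield NaN p with a flagged row rather
than an exception.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own validation protocol: 500 random tensors for
round trips; 1000 Monte-Carlo iterations for k_min; 500 null datasets for
the Gaussian-field FWE measurement; one seeded 18-vs-21 cohort for effect
detection plus 60 full null DWI cohorts for the cohort-level survival
rate; 500 replicates for correlation recovery. Stochastic checks assert
95% binomial (or ±0.05) bands at those sizes.

## Known limitations

* No positivity constraints on D or W; non-physical fits are flagged, not
  repaired.
* The Monte-Carlo null assumes stationary smoothness equal to the applied
  kernel; real data would need residual-based smoothness estimation.
* No covariate adjustment, permutation inference, or random-field-theory
  correction (out of scope by design).
* The forward model is the same truncated cumulant expansion the fit
  assumes, so round-trip tests cannot detect model misspecification —
  only estimator error.
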