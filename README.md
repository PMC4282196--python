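# dkivba

Diffusional kurtosis imaging (DKI) analysis at desk scale: kurtosis-tensor
estimation from multi-shell diffusion-weighted MRI, derivation of mean,
axial and radial kurtosis maps, voxel-based two-group comparison with
Monte-Carlo cluster-extent correction, ROI-wise brain–behaviour
correlation, and cohort clinical statistics — together with a synthetic
phantom/cohort generator so every step can be validated against known
ground truth.

## Who this is for

Researchers studying gray-matter microstructure with DKI — for example
comparing a clinical group (here modelled on an internet-gaming-addiction
cohort of 18 patients vs 21 controls) against healthy controls — who want a
transparent, scriptable, fully tested alternative to scanner-vendor black
boxes for the model fit and to GUI packages for the group statistics.

## The model

Along a diffusion-encoding direction **n** at b-value *b*, the DKI signal
model extends Gaussian (mono-exponential) decay with a quadratic term in
*b*:

```
ln S(b, n) = ln S0 − b·D_app(n) + (1/6)·b²·D_app(n)²·K_app(n)

D_app(n) = Σᵢⱼ nᵢnⱼ Dᵢⱼ                      (2nd-order diffusion tensor, 6 elements)
K_app(n) = (MD²/D_app(n)²)·Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ   (4th-order kurtosis tensor, 15 elements)
```

with MD = tr(D)/3. The 22 parameters (ln S0, D, V ≡ MD²·W) are estimated
per voxel by weighted linear least squares on the log-signal (one
reweighting pass, weights = squared predicted signal). Scalar maps:

* **MK** — K_app averaged over a direction set (acquired directions by
  default, dense 321-point sphere optionally);
* **K∥** (axial) — eigen-kurtosis along the principal diffusion
  eigenvector: K̂₁ = (MD²/λ₁²)·Ŵ₁₁₁₁, with Ŵ the kurtosis tensor rotated
  into the diffusion eigenframe;
* **K⊥** (radial) — mean of the two non-principal eigen-kurtoses.

Group inference is a voxelwise pooled-variance two-sample t-test at a
cluster-forming threshold (default two-tailed p < 0.001) followed by a
Monte-Carlo cluster-extent correction (AlphaSim-style): the minimum cluster
size k_min is the smallest extent whose family-wise occurrence rate over
simulated smooth Gaussian null fields does not exceed the corrected level
(default 0.05).

## Worked example

Simulate the default study: a 24³ phantom (2 mm voxels) of gray-matter-like
tissue (λ = (1.2, 1.0, 0.9)·10⁻³ mm²/s, MK ≈ 0.9) with a 5³-voxel lesion in
which the patient group's kurtosis tensor is halved, scanned at
b = 0/1000/2000 s/mm² with 25 directions per shell at SNR 46, for 18
patients vs 21 controls:

```python
from dkivba import make_scheme, default_phantom, EffectSpec, simulate_cohort
from dkivba.pipeline import analyze_cohort
from dkivba.vba import cluster_table, effect_recovery_report

scheme = make_scheme(25, [0, 1000, 2000])
spec = default_phantom(snr_b0=46.0)
vols, labels, truth = simulate_cohort(spec, EffectSpec("lesion", 0.5),
                                      18, 21, scheme, seed=42)
res = analyze_cohort(vols, labels, scheme, spec.tissue_mask(),
                     n_iter=1000, seed=0)
print("k_min =", res.k_min)
print(cluster_table(res.records).to_string(index=False))
print("hit rate:", effect_recovery_report(res.records,
                                          spec.region("lesion").mask)["hit_rate"])
```

prints

```
k_min = 11
region  peak_x_mm  peak_y_mm  peak_z_mm  n_voxels      peak_t
             12.0       11.0       12.0       786 -198.236177
hit rate: 1.0
```

i.e. the Monte-Carlo correction demands clusters of at least 11 voxels on
this mask at 6 mm smoothness; one large negative cluster (patients lower
than controls, hence t < 0) survives, centred on the lesion, covering all
of it. The extent is larger than the 125-voxel lesion because the 6 mm
smoothing spreads the effect.

The packaged per-subject clinical table reproduces the published group
statistics:

```bash
$ dkivba table1
                            variable     patients     controls          test      p
                         Age (years) 20.50 ± 3.55 21.95 ± 2.40  two-sample t 0.1382
                        Gender (M/F)         15/3         18/3    chi-square 0.8372
                   Education (years) 11.39 ± 1.85 12.38 ± 2.13  two-sample t 0.1326
Chen Internet Addiction Scale (CIAS) 74.44 ± 8.33 38.43 ± 9.10  two-sample t    0.0
     Self-Rating Anxiety Scale (SAS) 53.67 ± 9.71 40.95 ± 8.45  two-sample t 0.0001
    Self-rating depression scale (SDS) 54.33 ± 10.04 38.57 ± 6.67 two-sample t    0.0
Barratt Impulsiveness Scale-11 (BIS-11) 63.94 ± 8.26 50.81 ± 6.95 two-sample t    0.0
```

Other CLI entry points: `dkivba synth` (write a synthetic cohort as
NIfTI + FSL bvals/bvecs + CSV), `dkivba dkifit` (fit maps from files),
`dkivba mask`, `dkivba smooth`, and `dkivba vba` (the full group
comparison). See `dkivba --help`.

## Layout

| module | contents |
| --- | --- |
| `dkivba.gradients` | acquisition schemes, electrostatic-repulsion direction sets, FSL bval/bvec I/O |
| `dkivba.dki` | tensor algebra, WLLS fit, eigenframe transform, MK/K∥/K⊥ maps |
| `dkivba.phantom` | phantoms, DWI forward simulation with Rician noise, cohorts, clinical scores, packaged study table |
| `dkivba.spatial` | probability-threshold masks, FWHM Gaussian smoothing, grid checks |
| `dkivba.vba` | voxelwise t maps, Monte-Carlo cluster-extent threshold, cluster tables |
| `dkivba.roi` | ROI means, Pearson correlation with severity scores |
| `dkivba.clinical` | cohort demographic/clinical comparison table |
| `dkivba.pipeline` | the end-to-end cohort analysis |
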