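# Methods

## Model overview

`petacval` validates PET attenuation-correction (AC) methods by a
forward-simulate / reconstruct / compare loop carried out entirely on
synthetic data. The measurement model per sinogram bin is

```
ybar = τ · n · exp(−∫ μ_true dl) · P(x) + s,      y ~ Poisson(ybar)
```

where `P` is the forward projector (line integrals of the activity `x`),
`μ_true` the ground-truth CT-derived attenuation map, `n` a
multiplicative bin efficiency, `τ` a duration/sensitivity scale and `s`
a scatter term. Reconstruction inverts this model with OSEM, but with
the μ-map replaced by one of the MR-like variants; the regional activity
ratio against the CT-reconstructed image isolates the AC error, because
both reconstructions see the *same* counts realization.

## Phantom

The phantom is deliberately brain-LIKE, not anatomical: concentric
cylindrical shells (scalp soft tissue, skull bone, brain) with the brain
partitioned into angular wedges — an outer "cortical" annulus whose ROIs
touch the skull (`near_skull=True`) and an inner "deep" core. The atlas
geometry is fixed by the grid; the seed only perturbs per-ROI activity
(±10% around a 5 kBq/mL gray-matter background, scalp at 20% of that,
bone and air at zero), so a seed range acts like a patient cohort on a
common template. Default grid 128×128×16 at 2 mm — large enough for a
realistic head cross-section, small enough for interactive runs;
scanner-scale grids remain selectable through the config.

Shell parameters: scalp 6 mm, skull 8 mm. The skull thickness is at the
upper end of the adult cranial-vault range (diploë included) so that a
one-voxel erosion at 2 mm resolution removes half, not two-thirds, of
the bone — a thinner shell would make the model-based-bone variant
*worse* than the UTE-style variant, contrary to the behavior the
degradations are meant to emulate.

Tissue LACs at 511 keV (1/mm): air 0, fat 0.0090, soft tissue 0.0096,
cortical bone 0.0151 — standard published conversion values.

## MRAC-like degradation operators

The MRI acquisition, segmentation and learning steps of real MRAC
methods are out of scope; what matters for AC validation is the μ-map
error pattern each family produces:

| variant | operator | default parameters |
|---|---|---|
| `CTAC` | identity (reference) | — |
| `DIXON` | skull → soft-tissue μ | — |
| `DIXONBONE` | bone kept, scaled, eroded 1 in-plane voxel | scale 0.95 |
| `UTE` | whole head soft + one fixed bone class; seeded boundary flips | bone 0.0110 /mm, 20% flips |
| `DLDIXON` | voxelwise Gaussian μ noise, no systematic bone error | σ = 1% of soft μ |

The UTE single-class bone value (0.0110 /mm) and the erosion/flip
defaults were chosen once so that the mean |Δμ| over the skull ranks
`DIXON > UTE > DIXONBONE > DLDIXON > CTAC = 0` — the qualitative
ordering these method families show in practice — and are configurable.
With the defaults the skull-mean |Δμ| values are ≈ 5.5, 4.2, 2.9 and
0.08 ×10⁻³ /mm respectively.

## Projector

Multi-slice 2D parallel beam (96 angles over [0, π), 192 radial bins at
2 mm by default), replacing the vendor's 3D span/mashing geometry; the
validation logic is geometry-agnostic, and the projector sits behind a
forward/back-project contract so other geometries can be plugged in.
Rays are sampled at half the in-plane voxel pitch with bilinear
interpolation (Joseph-style), materialised as a sparse system matrix per
(geometry, grid); backprojection is its transpose, so the adjoint
identity holds to machine precision. Chord-length agreement on uniform
discs is ~0.5% at default sampling.

## Emission and noise

* **PSF** — lesions are smoothed with an isotropic 4 mm FWHM Gaussian
  (mMR-class resolution) before projection.
* **Attenuation** — applied as division by `ACF = exp(∫μ dl)` (trues
  model).
* **Scatter** — a stand-in for a full scatter simulation: the trues
  sinogram blurred radially with an 80 mm FWHM Gaussian and rescaled so
  the global scatter fraction is exactly the configured value (default
  0.3). Scatter is computed from the sinogram being composed.
* **Counts level** — `duration_scale` defaults to 0.08, which puts the
  default phantom at ≈2×10⁶ expected counts — the regime of a ~30 min
  brain acquisition at this grid scale. It is a pure scale; it is not
  calibrated to becquerels.
* **Randoms, dead time, TOF** — not modeled.
* **`replace` composition** — overwrites only bins inside the lesion's
  projection support (expected > 10⁻¹² of max), leaving all others
  untouched.

## Reconstruction

Ordinary-Poisson OSEM: scatter enters the denominator additively,
never pre-subtracted. Subsets are angle-interleaved (subset *k* takes
angles *k*, *k*+S, …); 96 angles / 24 subsets = 4 angles per subset.
Initialization is a uniform image inside the FOV support (voxels with
nonzero sensitivity); zero-sensitivity voxels are pinned to 0, and
denominators are floored at 10⁻¹². Defaults (3 it × 24 subsets, 4 mm
Gaussian post-filter) mirror a clinical brain protocol. Noiseless
matched-model reconstruction recovers interior ROI means within 2% at
10 it × 8 subsets, and the MLEM limit (1 subset) has a non-decreasing
Poisson log-likelihood.

## Experiment design and analysis

Three arms per phantom: `with_background` (lesion counts added to the
simulated emission background), `lesion_only`, and `original`
(no lesion; bias over the atlas ROIs). Within an arm, counts are drawn
**once** and every AC variant reconstructs the same realization — the
bias then reflects the attenuation model alone, and CTAC-vs-CTAC is
exactly zero by construction.

The default lesion layout is two 4 mm-radius spheres at a
lesion-to-background ratio of 2: one pushed to ~10 mm from the skull
inside a cortical ROI, one at the centroid of an interior ROI. ROI
means on lesion arms use the unsmoothed geometric sphere support, and
are taken on the post-filtered reconstruction (a flag disables the
filter). Cohort statistics are medians and type-7
(linear-interpolation) quartiles of the percent bias; CSV outputs round
to 2 decimals.

An 11-seed cohort stands in for an 11-patient dataset. At the default
desk scale the cohort reproduces the expected qualitative pattern —
every DIXON bias negative, |bias| larger near the skull, method ranking
`DIXON > UTE > DIXONBONE > DLDIXON`, and sign/rank agreement between
the with-background and lesion-only arms.

## What the synthetic data does and does not show

The generator reproduces the *mechanism* of MRAC bias (bone μ errors
propagating through the ACF into regional activity), with realistic
count levels, scatter fraction, PSF and noise. It does not reproduce
real anatomy (no air cavities, no continuous CT μ distribution, no
inter-subject anatomical variability), real MRAC segmentation failure
modes (susceptibility artifacts, mis-registration), randoms, or 3D
scanner geometry. Passing tests therefore demonstrate that the
*pipeline* measures AC bias correctly and that the degradation
operators produce the documented pattern — not that any specific
clinical method achieves a specific clinical bias value.

## Numerical choices

* Adjointness is exact (shared sparse matrix), tested to 1e-6 relative.
* Sphere/disc rasterization uses voxel-center inclusion; optional
  supersampling provides fractional edge occupancy for analytic
  validation objects. PSF smoothing handles edge softness downstream.
* Nearest-neighbor resampling breaks distance ties toward the lower
  source index (deterministic) and never invents values.
* The HU→LAC curve is bilinear through (−1000, 0), (0, 0.0096),
  (1000, 0.0151), clamped beyond; fully config-driven.
* Gaussian filters use reflective boundaries (constants preserved);
  σ = FWHM/2.3548 converted to voxels per axis.
* Registration is out of scope: external volumes must be pre-aligned.
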