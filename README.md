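# petacval

Synthetic-lesion validation of PET attenuation correction, on fully
generated digital brain phantoms.

## The problem

Quantitative brain PET on hybrid PET/MRI systems hinges on the
attenuation (μ) map used during reconstruction. MRI does not see
cortical bone, so every MR-derived attenuation correction (MRAC) —
Dixon tissue segmentation, Dixon plus a model-based bone prior,
ultra-short-echo-time (UTE) bone segmentation, or a deep-learning
pseudo-CT — misrepresents the skull to some degree, and the
reconstructed activity near bone is biased relative to the CT-based
reference (CTAC). Validating a new MRAC method normally requires
tri-modality (PET + MRI + CT) patient data, which is scarce.

`petacval` re-creates the alternative: insert *synthetic* lesions
directly in PET projection space, reconstruct them under each candidate
μ-map, and quantify the regional bias

```
bias = (PET_MRAC − PET_CTAC) / PET_CTAC      (reported in percent)
```

entirely without measured emission data. The package generates
brain-like phantoms (activity, labeled atlas, ground-truth CT μ-map),
emulates the four MRAC families as degradations of that μ-map, and runs
a three-arm experiment: lesions inserted **with** the emission
background, lesions reconstructed **alone**, and the **original**
(no-lesion) image.

## The pipeline

1. **phantom** — parametric head (scalp / skull / brain wedge ROIs with
   `near_skull` flags); μ at 511 keV: soft tissue 0.0096 /mm, bone
   0.0151 /mm. Degradations: `DIXON` (bone → water), `DIXONBONE`
   (bone ×0.95, eroded 1 voxel), `UTE` (single bone class 0.0110 /mm +
   20% boundary misclassification), `DLDIXON` (1% voxelwise μ noise),
   `CTAC` (identity).
2. **projection** — multi-slice 2D parallel-beam projector (sparse
   system matrix, exact adjoint pair), attenuation correction factors
   `ACF = exp(∫μ dl)`, bin-efficiency normalization.
3. **emission** — lesion activity volumes (absolute or
   lesion-to-background ratio, Gaussian PSF), expected counts
   `τ·n·P(x)/ACF` plus a scatter term at a fixed global scatter
   fraction, Poisson noise, and add / replace / lesion-only composition
   with a background sinogram.
4. **recon** — ordinary-Poisson OSEM (default 3 iterations × 24
   angle-interleaved subsets) with a 4 mm Gaussian post-filter.
5. **analysis** — ROI means, bias records, cohort medians/IQRs, the
   three-arm experiment driver and boxplot export.
6. **mumap_io** — HU→LAC piecewise-linear conversion, nearest-neighbor
   resampling, NIfTI / HDF5-sinogram / CSV / YAML-config plumbing.

## Worked example

```python
import petacval as pv
from petacval.analysis import (ExperimentSettings, default_cohort_lesions,
                               records_to_dataframe, run_experiment)
from petacval.recon import ReconParams

bundle = pv.generate_phantom(seed=1)                 # 128×128×16 @ 2 mm
variants = [pv.MracVariantSpec(n)
            for n in ("CTAC", "DIXON", "DIXONBONE", "UTE", "DLDIXON")]
records = run_experiment(bundle, default_cohort_lesions(bundle), variants,
                         ExperimentSettings(), ReconParams(), seed=1)
df = records_to_dataframe(records)
print(df.pivot_table(index=["arm", "roi"], columns="method",
                     values="bias_percent").round(2))
```

prints (seed 1; lesion arms show the two inserted 4 mm spheres, the
original arm the eight atlas ROIs — abridged):

```
method                            CTAC  DIXON  DIXONBONE  DLDIXON   UTE
arm             roi
lesion_only     fusiform           0.0  -8.46      -4.60     0.06 -6.34
                superior_frontal   0.0 -12.22      -6.56    -0.03 -9.25
original        fusiform           0.0  -6.06      -3.22    -0.01 -4.53
                superior_frontal   0.0 -10.57      -5.73    -0.01 -7.99
with_background fusiform           0.0  -6.48      -3.52    -0.15 -4.86
                superior_frontal   0.0 -12.84      -6.65    -0.01 -9.71
```

Reading it: the reference (CTAC vs itself) is identically zero; removing
bone entirely (DIXON) underestimates activity the most, and most
strongly for the lesion near the skull (`superior_frontal`); the UTE
and model-based-bone maps sit in between; the pseudo-CT (DLDIXON) is
nearly unbiased. The with-background and lesion-only arms agree in sign
and method ranking — the property that makes background-free synthetic
validation credible.

The same cohort run is available from the shell:

```sh
petacval run-all --seeds 1..11 --out results/   # bias_records.csv + bias_summary.csv
```

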