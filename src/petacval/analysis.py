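"""ROI statistics, MRAC-to-CTAC bias, cohort summaries and the experiment driver.

Bias of a reconstruction against the CT-based reference is

    bias = (PET_MRAC - PET_CTAC) / PET_CTAC

over an ROI mean, reported in percent.  The experiment driver mirrors a
three-arm validation design: lesions inserted on top of the emission
background, lesions reconstructed alone, and the original (no-lesion)
image — each reconstructed once per attenuation-map variant from the
*same* counts realization, so the bias isolates the attenuation error
from noise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import emission
from .emission import AcquisitionModel, LesionSpec, lesion_mask
from .phantom import MracVariantSpec, PhantomBundle, derive_mrac
from .projection import SinoGeometry, Sinogram, compute_acf, make_normalization
from .recon import ReconParams, osem
from .volumes import VoxelVolume

ARMS = ("with_background", "lesion_only", "original")


@dataclass
class BiasRecord:
    """One (phantom, AC method, arm, ROI) bias measurement."""

    phantom_id: int
    method: str
    arm: str
    roi: str
    mean_mrac: float
    mean_ctac: float

    @property
    def bias(self) -> float:
        return (self.mean_mrac - self.mean_ctac) / self.mean_ctac

    @property
    def bias_percent(self) -> float:
        return 100.0 * self.bias


@dataclass
class CohortSummary:
    method: str
    arm: str
    roi: str
    median_bias: float
    iqr: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        q1, q3 = self.iqr
        if not (q1 <= self.median_bias <= q3):
            raise ValueError("quartiles must bracket the median")


@dataclass
class ExperimentSettings:
    """Acquisition and simulation settings for one experiment run."""

    n_radial: int = 192
    radial_spacing: float = 2.0
    n_angles: int = 96
    scatter_fraction: float = emission.DEFAULT_SCATTER_FRACTION
    duration_scale: float = emission.DEFAULT_DURATION_SCALE
    norm_mode: str = "uniform"
    compose_mode: str = "add"
    noiseless: bool = False


def roi_mean(image: VoxelVolume, atlas: VoxelVolume, label: int) -> float:
    """Arithmetic mean of the image over one atlas label."""
    if not image.same_grid(atlas):
        from .mumap_io import resample_nearest

        atlas = resample_nearest(atlas, image)
    mask = atlas.data == label
    if not mask.any():
        inventory = np.unique(atlas.data).tolist()
        raise ValueError(f"label {label} absent from atlas; present labels: {inventory}")
    return float(image.data[mask].mean())


def bias(mean_mrac: float, mean_ctac: float) -> float:
    """(MRAC − CTAC)/CTAC, dimensionless (×100 for percent)."""
    if mean_ctac == 0:
        raise ValueError("reference (CTAC) ROI mean is zero; bias undefined")
    return (mean_mrac - mean_ctac) / mean_ctac


def records_to_dataframe(records: Iterable[BiasRecord]) -> pd.DataFrame:
    rows = [
        {
            "phantom_id": r.phantom_id,
            "method": r.method,
            "arm": r.arm,
            "roi": r.roi,
            "mean_mrac": r.mean_mrac,
            "mean_ctac": r.mean_ctac,
            "bias_percent": round(r.bias_percent, 2),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["phantom_id", "method", "arm", "roi", "mean_mrac", "mean_ctac", "bias_percent"],
    )


def cohort_summary(
    records: Sequence[BiasRecord],
    group_by: Sequence[str] = ("method", "arm", "roi"),
) -> list[CohortSummary]:
    """Median and linear-interpolation quartiles of bias percent per group.

    ``group_by`` may drop "roi" to pool ROIs within a method/arm.
    """
    if not records:
        warnings.warn("no bias records to summarize", stacklevel=2)
        return []
    df = records_to_dataframe(records)
    df["bias_percent"] = [r.bias_percent for r in records]  # unrounded for statistics
    out = []
    for key, grp in df.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        fields_ = dict(zip(group_by, key))
        vals = grp["bias_percent"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        out.append(
            CohortSummary(
                method=str(fields_.get("method", "pooled")),
                arm=str(fields_.get("arm", "pooled")),
                roi=str(fields_.get("roi", "pooled")),
                median_bias=float(med),
                iqr=(float(q1), float(q3)),
                n=len(vals),
            )
        )
    return out


def summary_to_dataframe(summaries: Iterable[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": s.method,
                "arm": s.arm,
                "roi": s.roi,
                "median_bias_percent": round(s.median_bias, 2),
                "q1_percent": round(s.iqr[0], 2),
                "q3_percent": round(s.iqr[1], 2),
                "n": s.n,
            }
            for s in summaries
        ]
    )


def _lesion_roi_name(spec: LesionSpec, bundle: PhantomBundle, index: int) -> str:
    if spec.shape == "atlas_roi":
        return bundle.label_name(spec.label)
    # name a sphere after the atlas ROI its center falls in
    atlas = bundle.atlas
    idx = tuple(
        int(round((spec.center[i] - atlas.origin[i]) / atlas.spacing[i])) for i in range(3)
    )
    if all(0 <= idx[i] < atlas.shape[i] for i in range(3)):
        return bundle.label_name(int(atlas.data[idx]))
    return f"lesion_{index}"


def run_experiment(
    bundle: PhantomBundle,
    lesions: Sequence[LesionSpec],
    variants: Sequence[MracVariantSpec],
    settings: ExperimentSettings = ExperimentSettings(),
    recon_params: ReconParams = ReconParams(),
    seed: int = 0,
    arms: Sequence[str] = ARMS,
) -> list[BiasRecord]:
    """Run the three-arm bias experiment on one phantom.

    Counts are simulated once per arm; only the μ-map used inside the
    reconstruction changes across variants, so every record compares
    reconstructions of identical data.  CTAC must be among the variants
    (it is the reference and yields exactly zero bias against itself).
    """
    names = [v.name for v in variants]
    if "CTAC" not in names:
        raise ValueError("variants must include CTAC, the reference method")
    for arm in arms:
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; expected subset of {ARMS}")

    ss = np.random.SeedSequence(seed)
    child = lambda: int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    geometry = SinoGeometry.for_volume(
        bundle.activity, settings.n_radial, settings.radial_spacing, settings.n_angles
    )
    norm = make_normalization(geometry, settings.norm_mode, seed=child())
    acf_true = compute_acf(bundle.mu_ct, geometry)
    true_model = AcquisitionModel(
        geometry, acf_true, norm, settings.scatter_fraction, settings.duration_scale
    )

    # one degraded μ-map (hence one recon model) per variant per phantom
    recon_models = {}
    for v in variants:
        mu_v = derive_mrac(bundle.mu_ct, bundle.atlas, v, seed=child())
        recon_models[v.name] = AcquisitionModel(
            geometry,
            compute_acf(mu_v, geometry),
            norm,
            settings.scatter_fraction,
            settings.duration_scale,
        )

    # lesion inventory shared by the two lesion arms
    lesion_volumes, lesion_masks, lesion_names = [], [], []
    for i, spec in enumerate(lesions):
        lesion_volumes.append(
            emission.lesion_activity_volume(spec, bundle.atlas, bundle.activity)
        )
        lesion_masks.append(lesion_mask(spec, bundle.atlas))
        lesion_names.append(_lesion_roi_name(spec, bundle, i))

    bg_trues, bg_scatter = emission.expected_counts_split(bundle.activity, true_model)
    records: list[BiasRecord] = []

    for arm in arms:
        if arm == "original":
            expected = bg_trues.copy_with(bg_trues.data + bg_scatter.data, "expected_counts")
            scatter_est = bg_scatter
            rois = [(bundle.label_name(l), bundle.atlas.data == l) for l in bundle.brain_labels()]
        else:
            if not lesions:
                continue
            l_trues = np.zeros(geometry.shape)
            l_scatter = np.zeros(geometry.shape)
            for vol in lesion_volumes:
                t, s = emission.expected_counts_split(vol, true_model)
                l_trues += t.data
                l_scatter += s.data
            if arm == "with_background":
                expected = bg_trues.copy_with(
                    bg_trues.data + bg_scatter.data + l_trues + l_scatter, "expected_counts"
                )
                scatter_est = bg_scatter.copy_with(bg_scatter.data + l_scatter, "scatter")
            else:  # lesion_only
                expected = bg_trues.copy_with(l_trues + l_scatter, "expected_counts")
                scatter_est = bg_scatter.copy_with(l_scatter, "scatter")
            rois = [
                (name, mask.data.astype(bool))
                for name, mask in zip(lesion_names, lesion_masks)
            ]

        if settings.noiseless:
            counts = expected
        else:
            counts = emission.add_poisson(expected, seed=child())

        recon_ctac = osem(counts, recon_models["CTAC"], scatter_est, recon_params, bundle.activity)
        for v in variants:
            img = (
                recon_ctac
                if v.name == "CTAC"
                else osem(counts, recon_models[v.name], scatter_est, recon_params, bundle.activity)
            )
            for roi_name, mask in rois:
                m_var = float(img.data[mask].mean())
                m_ref = float(recon_ctac.data[mask].mean())
                records.append(
                    BiasRecord(
                        phantom_id=bundle.seed,
                        method=v.name,
                        arm=arm,
                        roi=roi_name,
                        mean_mrac=m_var,
                        mean_ctac=m_ref,
                    )
                )
    return records


def default_cohort_lesions(
    bundle: PhantomBundle, psf_fwhm: float = emission.DEFAULT_PSF_FWHM
) -> list[LesionSpec]:
    """The standard two-lesion layout: 4 mm-radius spheres at LBR 2.

    One sphere sits in the first near-skull cortical ROI, pushed out along
    the wedge's mean direction to within ~10 mm of the skull (where
    attenuation errors from bone are largest); the other sits at the
    centroid of the first interior ROI.
    """
    cx, cy, cz = bundle.activity.center_world()
    specs = []
    for near in (True, False):
        label = bundle.brain_labels(near_skull=near)[0]
        if near:
            idx = np.argwhere(bundle.atlas.data == label)
            wx = bundle.atlas.origin[0] + idx[:, 0] * bundle.atlas.spacing[0] - cx
            wy = bundle.atlas.origin[1] + idx[:, 1] * bundle.atlas.spacing[1] - cy
            r = np.hypot(wx, wy)
            ang = np.arctan2(wy, wx)
            d = np.array([np.cos(ang).mean(), np.sin(ang).mean()])
            d /= np.linalg.norm(d)
            rad = float(r.max()) - 10.0
            center = (cx + d[0] * rad, cy + d[1] * rad, cz)
        else:
            cwx, cwy, _ = bundle.roi_centroid_world(label)
            center = (cwx, cwy, cz)
        specs.append(LesionSpec.sphere(center, 4.0, lbr=2.0, psf_fwhm=psf_fwhm))
    return specs


def plot_bias_boxplot(records: Sequence[BiasRecord], path: str, arm: Optional[str] = None) -> None:
    """Box plots of bias percent per method (optionally one arm), saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_dataframe(records)
    df["bias_percent"] = [r.bias_percent for r in records]
    if arm is not None:
        df = df[df["arm"] == arm]
    methods = [m for m in df["method"].unique() if m != "CTAC"]
    data = [df.loc[df["method"] == m, "bias_percent"] for m in methods]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=methods)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_ylabel("MRAC to CTAC bias (%)")
    ax.set_title(arm or "all arms")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
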