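"""Expected-counts modeling and sinogram-domain lesion insertion.

This is the heart of the validation pipeline: a lesion (sphere or atlas
ROI) is turned into an activity volume, smoothed with the scanner PSF,
forward projected, attenuated with the *true* μ-map and normalized,
given a scatter contribution and Poisson noise, and finally composed
with (added to / substituted into / used instead of) a background
emission sinogram.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantom import rasterize_sphere
from .projection import (
    SinoGeometry,
    Sinogram,
    forward_project,
    smooth_sinogram_radial,
)
from .volumes import VoxelVolume, gaussian_smooth

#: Default scanner point-spread-function FWHM, mm (mMR-class resolution).
DEFAULT_PSF_FWHM = 4.0
#: Default global scatter fraction scatter/(trues+scatter).
DEFAULT_SCATTER_FRACTION = 0.3
#: Radial FWHM (mm) of the broad Gaussian standing in for the scatter tail.
SCATTER_SMOOTH_FWHM = 80.0
#: Default activity→expected-counts scale.  With the default phantom
#: (5 kBq/mL gray matter, 128×128×16 grid at 2 mm) this yields ~2e6 total
#: expected counts — the count regime of a ~30 min brain acquisition at
#: desk scale.
DEFAULT_DURATION_SCALE = 0.08


@dataclass
class LesionSpec:
    """Geometry + activity rule for one inserted lesion.

    ``shape`` is ``"sphere"`` (with ``center`` mm world and ``radius`` mm)
    or ``"atlas_roi"`` (with ``label``).  The activity rule is either an
    absolute concentration (Bq/mL) or a lesion-to-background ratio (LBR)
    applied to the mean background activity over the lesion support.
    """

    shape: str
    center: Optional[tuple[float, float, float]] = None
    radius: Optional[float] = None
    label: Optional[int] = None
    absolute: Optional[float] = None
    lbr: Optional[float] = None
    psf_fwhm: float = DEFAULT_PSF_FWHM

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "atlas_roi"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if self.shape == "sphere":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("sphere lesion needs a center and a positive radius")
        else:
            if self.label is None:
                raise ValueError("atlas_roi lesion needs a label id")
        if (self.absolute is None) == (self.lbr is None):
            raise ValueError("exactly one of absolute= or lbr= must be given")
        if self.lbr is not None and self.lbr <= 0:
            raise ValueError(f"lesion-to-background ratio must be > 0, got {self.lbr}")

    @classmethod
    def sphere(cls, center, radius, *, absolute=None, lbr=None, psf_fwhm=DEFAULT_PSF_FWHM):
        return cls("sphere", center=tuple(center), radius=float(radius),
                   absolute=absolute, lbr=lbr, psf_fwhm=psf_fwhm)

    @classmethod
    def atlas_roi(cls, label, *, absolute=None, lbr=None, psf_fwhm=DEFAULT_PSF_FWHM):
        return cls("atlas_roi", label=int(label),
                   absolute=absolute, lbr=lbr, psf_fwhm=psf_fwhm)


@dataclass
class AcquisitionModel:
    """Everything between an activity volume and an expected-counts sinogram."""

    geometry: SinoGeometry
    acf: Sinogram
    norm: Sinogram
    scatter_fraction: float = DEFAULT_SCATTER_FRACTION
    duration_scale: float = DEFAULT_DURATION_SCALE

    def __post_init__(self) -> None:
        if not (0.0 <= self.scatter_fraction < 1.0):
            raise ValueError(f"scatter fraction must be in [0, 1), got {self.scatter_fraction}")
        if self.acf.geometry != self.geometry or self.norm.geometry != self.geometry:
            raise ValueError("acf and norm must share the model geometry")
        if self.acf.role != "acf" or self.norm.role != "normalization":
            raise ValueError("acf/norm sinograms carry the wrong role tags")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")


def lesion_mask(spec: LesionSpec, atlas: VoxelVolume) -> VoxelVolume:
    """Binary geometric support of the lesion (pre-PSF)."""
    if spec.shape == "sphere":
        return rasterize_sphere(atlas, spec.center, spec.radius)
    mask = (atlas.data == spec.label).astype(np.uint8)
    if not mask.any():
        raise ValueError(f"label {spec.label} not present in atlas")
    return atlas.copy_with(mask)


def lesion_activity_volume(
    spec: LesionSpec,
    atlas: VoxelVolume,
    background_activity: Optional[VoxelVolume] = None,
) -> VoxelVolume:
    """Activity volume of one lesion: value on the mask, PSF-smoothed.

    The LBR rule requires a background image: the lesion concentration is
    (mean background over the mask) × ratio, the convention used when a
    lesion is specified relative to local uptake.
    """
    mask = lesion_mask(spec, atlas).data.astype(bool)
    if not mask.any():
        raise ValueError("lesion mask is empty (outside the grid?)")
    if spec.absolute is not None:
        value = float(spec.absolute)
    else:
        if background_activity is None:
            raise ValueError("LBR activity rule requires a background activity image")
        if not background_activity.same_grid(atlas):
            raise ValueError("background activity and atlas must share a grid")
        bg_mean = float(background_activity.data[mask].mean())
        if bg_mean <= 0:
            raise ValueError("background mean over the lesion mask is zero")
        value = bg_mean * float(spec.lbr)
    vol = atlas.copy_with(np.where(mask, value, 0.0))
    return gaussian_smooth(vol, spec.psf_fwhm)


def expected_counts_split(
    activity: VoxelVolume, model: AcquisitionModel
) -> tuple[Sinogram, Sinogram]:
    """(trues, scatter) expected-counts pair.

    trues = duration_scale · norm · P(activity) / acf.  Scatter is a broad
    radial Gaussian of the trues, rescaled so that globally
    scatter / (trues + scatter) equals the model's scatter fraction.
    """
    if np.any(activity.data < 0):
        raise ValueError("activity must be non-negative")
    li = forward_project(activity, model.geometry)
    trues = model.duration_scale * model.norm.data * li.data / model.acf.data
    sf = model.scatter_fraction
    trues_total = trues.sum()
    if sf > 0 and trues_total > 0:
        blur = smooth_sinogram_radial(trues, model.geometry, SCATTER_SMOOTH_FWHM)
        scatter = blur * (sf / (1.0 - sf) * trues_total / blur.sum())
    else:
        scatter = np.zeros_like(trues)
    return (
        Sinogram(trues, model.geometry, "expected_counts"),
        Sinogram(scatter, model.geometry, "scatter"),
    )


def expected_counts(activity: VoxelVolume, model: AcquisitionModel) -> Sinogram:
    """Total expected counts (trues + scatter)."""
    trues, scatter = expected_counts_split(activity, model)
    return Sinogram(trues.data + scatter.data, model.geometry, "expected_counts")


def add_poisson(expected: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per bin, reproducible under the seed."""
    if np.any(expected.data < 0):
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.data)
    return Sinogram(counts.astype(np.int64), expected.geometry, "counts")


def lesion_support_mask(lesion_expected: Sinogram, rel_threshold: float = 1e-12) -> np.ndarray:
    """Bins the lesion projects into: expected > rel_threshold × max."""
    m = lesion_expected.data.max()
    return lesion_expected.data > rel_threshold * m if m > 0 else np.zeros(
        lesion_expected.data.shape, dtype=bool
    )


def compose(
    background: Optional[Sinogram],
    lesion_expected: Sinogram,
    mode: str = "add",
    support_mask: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Sinogram:
    """Combine a Poisson draw of the lesion with the background counts.

    ``add`` — lesion counts added on top of the background (the realistic
    arm); ``replace`` — background bins inside the lesion's projection
    support overwritten by the lesion draw; ``lesion_only`` — the lesion
    draw alone, background ignored.
    """
    if mode not in ("add", "replace", "lesion_only"):
        raise ValueError(f"unknown compose mode {mode!r}")
    draw = add_poisson(lesion_expected, seed)
    if mode == "lesion_only":
        return draw
    if background is None:
        raise ValueError(f"mode {mode!r} requires a background counts sinogram")
    if background.geometry != lesion_expected.geometry:
        raise ValueError("background and lesion sinograms must share geometry")
    if background.role != "counts":
        raise ValueError("background must carry the counts role")
    if mode == "add":
        return background.copy_with(background.data + draw.data)
    mask = support_mask if support_mask is not None else lesion_support_mask(lesion_expected)
    out = background.data.copy()
    out[mask] = draw.data[mask]
    return background.copy_with(out)
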