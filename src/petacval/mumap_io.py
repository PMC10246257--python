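"""μ-map preprocessing and file plumbing.

Externally supplied CT (or pseudo-CT) volumes arrive in Hounsfield units
and on their own grid; this module converts them to 511 keV linear
attenuation coefficients by piecewise-linear (bilinear) scaling and
resamples them with nearest-neighbor interpolation onto the target grid.

External inputs are assumed PRE-ALIGNED to the activity grid: this
toolkit performs no registration.  NIfTI I/O honors the header affine
but requires axis-aligned (diagonal, positive) orientations.
"""
from __future__ import annotations

import contextlib
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Union

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import MU_SOFT, MU_BONE
from .projection import SinoGeometry, Sinogram
from .volumes import VoxelVolume

log = logging.getLogger("petacval")

#: Default bilinear HU→LAC curve: air → water → dense-bone, clamped beyond.
DEFAULT_HU_BREAKPOINTS = ((-1000.0, 0.0), (0.0, MU_SOFT), (1000.0, MU_BONE))


@dataclass
class HuToLacCurve:
    """Piecewise-linear map from Hounsfield units to 511 keV LAC (1/mm).

    Extrapolation clamps to the end segments' values.
    """

    breakpoints: tuple = DEFAULT_HU_BREAKPOINTS

    def __post_init__(self) -> None:
        bp = tuple((float(h), float(l)) for h, l in self.breakpoints)
        if len(bp) < 2:
            raise ValueError("need at least two breakpoints")
        hu = np.array([h for h, _ in bp])
        lac = np.array([l for _, l in bp])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(np.diff(lac) < 0):
            raise ValueError("LAC values must be non-decreasing")
        at_water = float(np.interp(0.0, hu, lac))
        if abs(at_water - MU_SOFT) > 1e-4:
            raise ValueError(
                f"curve must pass through (0 HU, {MU_SOFT} /mm) within 1e-4; got {at_water}"
            )
        self.breakpoints = bp
        self._hu = hu
        self._lac = lac

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.clip(np.interp(hu, self._hu, self._lac), 0.0, None)


def hu_to_lac(hu_image: VoxelVolume, curve: Optional[HuToLacCurve] = None) -> VoxelVolume:
    """Convert an HU image to a μ-map (1/mm); monotone, clamped ≥ 0."""
    curve = curve or HuToLacCurve()
    return hu_image.copy_with(curve(hu_image.data.astype(np.float64)))


def resample_nearest(
    volume: VoxelVolume,
    target: Union[VoxelVolume, tuple],
) -> VoxelVolume:
    """Nearest-neighbor resampling onto a target grid.

    ``target`` is a grid-defining VoxelVolume or a (shape, spacing,
    origin) tuple.  Each target voxel takes the value of the source voxel
    whose center is nearest in world coordinates; equidistant ties go to
    the lower source index; target voxels outside the source grid get 0.
    Integer (label) dtypes are preserved — no new values are invented.
    """
    if isinstance(target, VoxelVolume):
        shape, spacing, origin = target.shape, target.spacing, target.origin
    else:
        shape, spacing, origin = target
    idx = []
    inside = np.ones((), dtype=bool)
    for ax in range(3):
        centers = origin[ax] + spacing[ax] * np.arange(shape[ax])
        f = (centers - volume.origin[ax]) / volume.spacing[ax]
        i = np.ceil(f - 0.5).astype(np.int64)  # tie → lower index
        ok = (i >= 0) & (i < volume.shape[ax])
        sl = [None, None, None]
        sl[ax] = slice(None)
        idx.append(np.clip(i, 0, volume.shape[ax] - 1)[tuple(sl)])
        inside = inside & ok[tuple(sl)]
    if not np.any(inside):
        raise ValueError("target grid does not overlap the source grid")
    out = volume.data[idx[0], idx[1], idx[2]]
    fill = np.zeros((), dtype=volume.data.dtype)
    out = np.where(inside, out, fill)
    return VoxelVolume(out, spacing, origin)


# --------------------------------------------------------------------------
# NIfTI volumes


def write_nifti(vol: VoxelVolume, path: str) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asanyarray(vol.data), affine)
    nib.save(img, path)


def read_nifti(path: str) -> VoxelVolume:
    img = nib.load(path)
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
        raise ValueError(
            f"{path}: oblique/rotated affines are not supported; resample to an "
            "axis-aligned grid first"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine must have positive diagonal spacing")
    data = np.asanyarray(img.dataobj)
    return VoxelVolume(data, tuple(spacing), tuple(affine[:3, 3]))


# --------------------------------------------------------------------------
# sinogram container (single-file HDF5 with geometry metadata)


def save_sinogram(sino: Sinogram, path: str) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=sino.data, compression="gzip")
        d.attrs["role"] = sino.role
        g = sino.geometry
        for k in ("n_radial", "radial_spacing", "n_angles", "n_slices", "slice_spacing"):
            d.attrs[k] = getattr(g, k)


def load_sinogram(path: str) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["data"]
        geo = SinoGeometry(
            n_radial=int(d.attrs["n_radial"]),
            radial_spacing=float(d.attrs["radial_spacing"]),
            n_angles=int(d.attrs["n_angles"]),
            n_slices=int(d.attrs["n_slices"]),
            slice_spacing=float(d.attrs["slice_spacing"]),
        )
        return Sinogram(d[...], geo, str(d.attrs["role"]))


def export_sinogram_csv(sino: Sinogram, path: str, slice_index: int = 0) -> None:
    """2D (angle × radial) CSV of one slice, for debugging."""
    np.savetxt(path, sino.data[:, :, slice_index], delimiter=",")


# --------------------------------------------------------------------------
# config + stage timing


def default_config() -> dict:
    from . import emission, phantom

    return {
        "tissue_lac": {
            "air": phantom.MU_AIR,
            "soft": phantom.MU_SOFT,
            "fat": phantom.MU_FAT,
            "bone": phantom.MU_BONE,
            "bone_ute": phantom.MU_BONE_UTE,
        },
        "hu_curve_breakpoints": [list(bp) for bp in DEFAULT_HU_BREAKPOINTS],
        "phantom": {"grid": [128, 128, 16], "spacing": [2.0, 2.0, 2.0], "n_rois": 8},
        "geometry": {"n_radial": 192, "radial_spacing": 2.0, "n_angles": 96},
        "recon": {"n_iterations": 3, "n_subsets": 24, "post_filter_fwhm": 4.0},
        "emission": {
            "scatter_fraction": emission.DEFAULT_SCATTER_FRACTION,
            "duration_scale": emission.DEFAULT_DURATION_SCALE,
            "psf_fwhm": emission.DEFAULT_PSF_FWHM,
        },
        "degradation": {
            "DIXONBONE": {"bone_scale": 0.95, "erosion_voxels": 1},
            "UTE": {"bone_mu": 0.0110, "misclassification_fraction": 0.2},
            "DLDIXON": {"noise_sigma_fraction": 0.01},
        },
        "seeds": list(range(1, 12)),
    }


def load_config(path: Optional[str]) -> dict:
    """Merge a YAML config file (top-level keys) over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


@contextlib.contextmanager
def stage(name: str):
    """Log per-stage wall time."""
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    finally:
        log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
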