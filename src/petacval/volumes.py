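"""Voxel-grid container shared by every stage of the pipeline.

A :class:`VoxelVolume` is a plain 3D scalar grid with physical metadata:
voxel spacing in mm and the world coordinate of the *center* of voxel
(0, 0, 0).  Specialised roles (activity in Bq/mL, linear attenuation in
1/mm, Hounsfield units, integer label atlas) are conventions on the data,
not subclasses; `validate_*` helpers enforce the role invariants where a
stage requires them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sanity ceiling for a 511 keV μ-map, 1/mm — comfortably above cortical bone.
MU_MAX = 0.05


@dataclass
class VoxelVolume:
    """A 3D scalar grid with voxel spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : tuple of float
        Voxel pitch (dx, dy, dz) in mm; strictly positive.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        """True if shape, spacing and origin all match within ``atol`` mm."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def center_world(self) -> tuple[float, float, float]:
        """World coordinate of the geometric center of the grid."""
        return tuple(
            self.origin[i] + self.spacing[i] * (self.shape[i] - 1) / 2.0
            for i in range(3)
        )

    def copy_with(self, data: np.ndarray) -> "VoxelVolume":
        """New volume on the same grid with different data."""
        if data.shape != self.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {self.shape}")
        return VoxelVolume(np.array(data), self.spacing, self.origin)


#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


def gaussian_smooth(vol: VoxelVolume, fwhm_mm: float) -> VoxelVolume:
    """Isotropic Gaussian blur of a volume, FWHM in mm; fwhm=0 is identity.

    Sigma is converted per axis to voxel units by the spacing; reflective
    boundaries preserve constants and (away from edges) total mass.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy_with(vol.data.astype(np.float64, copy=True))
    from scipy import ndimage  # local import keeps module load light

    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in vol.spacing]
    return vol.copy_with(ndimage.gaussian_filter(vol.data.astype(np.float64), sigma_vox, mode="reflect"))


def validate_activity(vol: VoxelVolume) -> None:
    if np.any(vol.data < 0):
        raise ValueError("activity image must be non-negative everywhere")


def validate_mumap(vol: VoxelVolume) -> None:
    if np.any(vol.data < 0):
        raise ValueError("μ-map must be non-negative everywhere")
    if np.any(vol.data > MU_MAX):
        raise ValueError(f"μ-map exceeds the sanity ceiling of {MU_MAX} /mm")


def validate_atlas(vol: VoxelVolume) -> None:
    if not np.issubdtype(vol.data.dtype, np.integer):
        raise ValueError("label atlas must hold an integer dtype")
    if np.any(vol.data < 0):
        raise ValueError("label atlas must contain only non-negative integers")
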