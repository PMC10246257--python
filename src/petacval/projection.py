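"""Projection-space geometry and the forward/back projector pair.

The scanner's true 3D sinogram (span, mashing, oblique segments) is
replaced by a documented multi-slice 2D parallel-beam model: every slice
of the volume is projected independently onto ``n_angles`` uniform view
angles over [0, π) and ``n_radial`` radial bins.

The projector is ray-driven with bilinear in-plane interpolation (Joseph
style sampling at half-voxel steps) and is materialised as a sparse
system matrix per (geometry, grid) pair.  Back projection is the exact
transpose of that matrix, so the adjoint identity

    <A x, y> == <x, A^T y>

holds to machine precision — the numeric contract OSEM relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, sparse

from .volumes import VoxelVolume

SINOGRAM_ROLES = (
    "line_integrals",
    "acf",
    "normalization",
    "scatter",
    "expected_counts",
    "counts",
)


@dataclass(frozen=True)
class SinoGeometry:
    """Parallel-beam projection geometry.

    Angles are uniform over [0, π); radial bins are centered on the
    rotation axis with pitch ``radial_spacing`` mm; slices map one-to-one
    onto volume slices at ``slice_spacing`` mm.
    """

    n_radial: int = 192
    radial_spacing: float = 2.0
    n_angles: int = 96
    n_slices: int = 16
    slice_spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.n_radial < 2 or self.n_angles < 1 or self.n_slices < 1:
            raise ValueError(f"degenerate geometry {self}")
        if self.radial_spacing <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be strictly positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def radial_offsets(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_spacing

    @property
    def fov_mm(self) -> float:
        return self.n_radial * self.radial_spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial, self.n_slices)

    @classmethod
    def for_volume(
        cls,
        volume: VoxelVolume,
        n_radial: int = 192,
        radial_spacing: float = 2.0,
        n_angles: int = 96,
    ) -> "SinoGeometry":
        """Default geometry with slices matched to ``volume``."""
        return cls(
            n_radial=n_radial,
            radial_spacing=radial_spacing,
            n_angles=n_angles,
            n_slices=volume.shape[2],
            slice_spacing=volume.spacing[2],
        )


@dataclass
class Sinogram:
    """Projection-space data (n_angles, n_radial, n_slices) with a role tag."""

    data: np.ndarray
    geometry: SinoGeometry
    role: str = "line_integrals"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )
        if self.role not in SINOGRAM_ROLES:
            raise ValueError(f"unknown sinogram role {self.role!r}")
        if self.role == "counts":
            if np.any(self.data < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("counts must be integers")
        elif self.role == "acf":
            if np.any(self.data < 1.0 - 1e-9):
                raise ValueError("attenuation correction factors must be >= 1")
        elif self.role == "normalization":
            if np.any(self.data <= 0):
                raise ValueError("normalization efficiencies must be > 0")

    def copy_with(self, data: np.ndarray, role: Optional[str] = None) -> "Sinogram":
        return Sinogram(np.array(data), self.geometry, role or self.role)

    def total(self) -> float:
        return float(self.data.sum())


# --------------------------------------------------------------------------
# system matrix


class Projector:
    """Sparse system matrix for one (geometry, in-plane grid) pair.

    The matrix maps a flattened (nx*ny) slice to a flattened
    (n_angles*n_radial) slice sinogram; a 3D volume is handled as a
    (nx*ny, nz) matmul.  Rays are centered on the volume's in-plane
    center, sampled at half the smaller in-plane voxel pitch, each sample
    spreading over its 4 bilinear neighbours weighted by the step length.
    """

    def __init__(
        self,
        geometry: SinoGeometry,
        shape_xy: tuple[int, int],
        spacing_xy: tuple[float, float],
    ):
        self.geometry = geometry
        self.shape_xy = (int(shape_xy[0]), int(shape_xy[1]))
        self.spacing_xy = (float(spacing_xy[0]), float(spacing_xy[1]))
        nx, ny = self.shape_xy
        dx, dy = self.spacing_xy
        diag = float(np.hypot(nx * dx, ny * dy))
        if geometry.fov_mm < diag:
            raise ValueError(
                f"geometry FOV {geometry.fov_mm:.0f} mm does not cover the "
                f"volume's transaxial diagonal {diag:.0f} mm"
            )
        self.matrix = self._build()
        self._subsets: dict[int, list[tuple[np.ndarray, sparse.csr_matrix, sparse.csr_matrix]]] = {}

    def _build(self) -> sparse.csr_matrix:
        geo = self.geometry
        nx, ny = self.shape_xy
        dx, dy = self.spacing_xy
        cx = dx * (nx - 1) / 2.0
        cy = dy * (ny - 1) / 2.0
        step = 0.5 * min(dx, dy)
        half = float(np.hypot(nx * dx, ny * dy)) / 2.0 + step
        t = np.arange(-half, half + step / 2, step)
        r = geo.radial_offsets

        blocks = []
        n_cols = nx * ny
        for theta in geo.angles:
            ux, uy = np.cos(theta), np.sin(theta)
            vx, vy = -np.sin(theta), np.cos(theta)
            # sample positions for all radial bins at once: (n_radial, n_t)
            px = cx + r[:, None] * ux + t[None, :] * vx
            py = cy + r[:, None] * uy + t[None, :] * vy
            fx = px / dx
            fy = py / dy
            ix = np.floor(fx).astype(np.int64)
            iy = np.floor(fy).astype(np.int64)
            wx = fx - ix
            wy = fy - iy
            ok = (ix >= 0) & (ix < nx - 1) & (iy >= 0) & (iy < ny - 1)
            rows_bin = np.broadcast_to(
                np.arange(geo.n_radial)[:, None], ix.shape
            )[ok]
            ix, iy, wx, wy = ix[ok], iy[ok], wx[ok], wy[ok]
            base = ix * ny + iy
            cols = np.concatenate([base, base + ny, base + 1, base + ny + 1])
            wts = np.concatenate(
                [
                    (1 - wx) * (1 - wy),
                    wx * (1 - wy),
                    (1 - wx) * wy,
                    wx * wy,
                ]
            ) * step
            rows = np.tile(rows_bin, 4)
            block = sparse.coo_matrix(
                (wts, (rows, cols)), shape=(geo.n_radial, n_cols)
            ).tocsr()
            blocks.append(block)
        a = sparse.vstack(blocks, format="csr")
        a.sum_duplicates()
        return a

    # -- application --------------------------------------------------------

    def forward(self, volume: VoxelVolume) -> Sinogram:
        self._check_slices(volume.shape[2], volume.spacing[2])
        nx, ny, nz = volume.shape
        flat = volume.data.reshape(nx * ny, nz)
        sino = self.matrix @ flat  # (n_angles*n_radial, nz)
        data = sino.reshape(self.geometry.n_angles, self.geometry.n_radial, nz)
        return Sinogram(data, self.geometry, "line_integrals")

    def back(self, sino: Sinogram, grid_like: VoxelVolume) -> VoxelVolume:
        self._check_slices(grid_like.shape[2], grid_like.spacing[2])
        if sino.geometry != self.geometry:
            raise ValueError("sinogram geometry does not match projector geometry")
        nx, ny, nz = grid_like.shape
        flat = sino.data.reshape(-1, nz)
        img = self.matrix.T @ flat
        return grid_like.copy_with(img.reshape(nx, ny, nz))

    def _check_slices(self, nz: int, dz: float) -> None:
        if nz != self.geometry.n_slices:
            raise ValueError(
                f"volume has {nz} slices but geometry expects {self.geometry.n_slices}"
            )
        if not np.isclose(dz, self.geometry.slice_spacing):
            raise ValueError(
                f"volume slice spacing {dz} mm != geometry {self.geometry.slice_spacing} mm"
            )

    # -- subsets ------------------------------------------------------------

    def subsets(
        self, n_subsets: int
    ) -> list[tuple[np.ndarray, sparse.csr_matrix, sparse.csr_matrix]]:
        """Angle-interleaved subset system matrices.

        Returns, per subset, (angle indices, A_s, A_s^T) where subset k
        takes angles k, k + n_subsets, ...
        """
        if self.geometry.n_angles % n_subsets != 0:
            raise ValueError(
                f"n_angles={self.geometry.n_angles} not divisible by n_subsets={n_subsets}"
            )
        if n_subsets not in self._subsets:
            out = []
            for k in range(n_subsets):
                ang = np.arange(k, self.geometry.n_angles, n_subsets)
                rows = (
                    ang[:, None] * self.geometry.n_radial
                    + np.arange(self.geometry.n_radial)[None, :]
                ).ravel()
                a_s = self.matrix[rows]
                out.append((ang, a_s, a_s.T.tocsr()))
            self._subsets[n_subsets] = out
        return self._subsets[n_subsets]


_PROJECTOR_CACHE: dict[tuple, Projector] = {}


def get_projector(geometry: SinoGeometry, volume: VoxelVolume) -> Projector:
    """Cached projector for this geometry and the volume's in-plane grid."""
    key = (geometry, volume.shape[:2], volume.spacing[:2])
    if key not in _PROJECTOR_CACHE:
        if len(_PROJECTOR_CACHE) > 8:
            _PROJECTOR_CACHE.clear()
        _PROJECTOR_CACHE[key] = Projector(geometry, volume.shape[:2], volume.spacing[:2])
    return _PROJECTOR_CACHE[key]


# --------------------------------------------------------------------------
# public operations


def forward_project(volume: VoxelVolume, geometry: SinoGeometry) -> Sinogram:
    """Line integrals (value·mm) of the volume along every transaxial ray."""
    return get_projector(geometry, volume).forward(volume)


def back_project(sino: Sinogram, grid_like: VoxelVolume) -> VoxelVolume:
    """Adjoint of :func:`forward_project` onto the grid of ``grid_like``."""
    return get_projector(sino.geometry, grid_like).back(sino, grid_like)


def compute_acf(mu_map: VoxelVolume, geometry: SinoGeometry) -> Sinogram:
    """Attenuation correction factors exp(∫ μ dl) per ray; all bins >= 1.

    Dividing a trues sinogram by the ACF applies attenuation; multiplying
    measured trues by the ACF corrects it.
    """
    if np.any(mu_map.data < 0):
        raise ValueError("μ-map contains negative values")
    li = forward_project(mu_map, geometry)
    return Sinogram(np.exp(li.data), geometry, "acf")


def make_normalization(
    geometry: SinoGeometry, mode: str = "uniform", seed: int = 0
) -> Sinogram:
    """Per-bin detection efficiencies.

    ``uniform`` → all ones; ``seeded_efficiency`` → reproducible draws in
    [0.9, 1.1] emulating crystal efficiency variation.
    """
    if mode == "uniform":
        data = np.ones(geometry.shape)
    elif mode == "seeded_efficiency":
        rng = np.random.default_rng(seed)
        data = rng.uniform(0.9, 1.1, size=geometry.shape)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Sinogram(data, geometry, "normalization")


def smooth_sinogram_radial(sino_data: np.ndarray, geometry: SinoGeometry, fwhm_mm: float) -> np.ndarray:
    """Gaussian smoothing along the radial axis, reflective boundary."""
    if fwhm_mm <= 0:
        return sino_data.copy()
    sigma_bins = fwhm_mm / 2.3548200450309493 / geometry.radial_spacing
    return ndimage.gaussian_filter1d(sino_data, sigma_bins, axis=1, mode="reflect")
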