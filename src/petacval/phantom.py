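"""Digital brain-like phantom generation and MRAC-style μ-map degradation.

The phantom is a parametric head: an outer scalp shell of soft tissue, a
skull shell of bone, and a brain interior partitioned into named angular
ROIs (an outer "cortical" annulus touching the skull, flagged
``near_skull``, and an inner "deep" core).  Activity is a uniform
gray-matter background with seeded per-ROI perturbations; bone and air
carry no activity.

The four MR-based attenuation-map families are emulated as degradation
operators on the ground-truth CT μ-map:

* ``DIXON`` — tissue segmentation without bone: every skull voxel is
  replaced by soft-tissue μ.
* ``DIXONBONE`` — model-based bone added to a Dixon map: bone retained
  but underscaled (default ×0.95) and eroded by one in-plane voxel, since
  a registered bone model never matches the true skull exactly.
* ``UTE`` — two-compartment segmentation from ultra-short-echo-time
  imaging: a single fixed bone LAC for the whole skull plus seeded
  misclassification of a fraction of boundary voxels.
* ``DLDIXON`` — deep-learning pseudo-CT: no systematic bone error, just
  small voxelwise noise.
* ``CTAC`` — the identity (reference) transform.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import VoxelVolume

# -- tissue linear attenuation coefficients at 511 keV, 1/mm ---------------
MU_AIR = 0.0
MU_SOFT = 0.0096
MU_FAT = 0.0090
MU_BONE = 0.0151
#: Single-class bone LAC assigned by the UTE-style segmentation (1/mm).
#: UTE maps are known to under-represent cortical bone density.
MU_BONE_UTE = 0.0110

#: Gray-matter background activity, nominal kBq/mL.
BACKGROUND_ACTIVITY = 5.0
#: Scalp soft tissue carries modest extracerebral uptake.
SCALP_ACTIVITY_FRACTION = 0.2

# special structural labels
LABEL_AIR = 0
LABEL_SCALP = 1
LABEL_SKULL = 2
FIRST_BRAIN_LABEL = 3

_CORTICAL_NAMES = [
    "superior_frontal", "parietal", "temporal", "occipital",
    "inferior_frontal", "precentral", "postcentral", "cingulate",
]
_DEEP_NAMES = [
    "fusiform", "thalamus", "caudate", "putamen",
    "white_matter", "hippocampus", "insula", "brainstem",
]

# default shell thicknesses, mm
SCALP_THICKNESS_MM = 6.0
SKULL_THICKNESS_MM = 8.0

VARIANT_NAMES = ("CTAC", "DIXON", "DIXONBONE", "UTE", "DLDIXON")


@dataclass
class MracVariantSpec:
    """One attenuation-map method to emulate.

    ``parameters`` overrides the per-variant degradation defaults:
    DIXONBONE: ``bone_scale`` (0.95), ``erosion_voxels`` (1);
    UTE: ``bone_mu`` (MU_BONE_UTE), ``misclassification_fraction`` (0.2);
    DLDIXON: ``noise_sigma_fraction`` (0.01, of soft-tissue μ).
    """

    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.name = self.name.upper().replace("-", "").replace("_", "")
        if self.name not in VARIANT_NAMES:
            raise ValueError(
                f"unknown MRAC variant {self.name!r}; expected one of {VARIANT_NAMES}"
            )


@dataclass
class PhantomBundle:
    """Activity + atlas + ground-truth μ-map on one common grid."""

    activity: VoxelVolume
    atlas: VoxelVolume
    labels: pd.DataFrame  # columns: id, name, near_skull
    mu_ct: VoxelVolume
    seed: int

    def __post_init__(self) -> None:
        if not (self.activity.same_grid(self.atlas) and self.activity.same_grid(self.mu_ct)):
            raise ValueError("activity, atlas and mu_ct must share one grid")
        present = set(np.unique(self.atlas.data).tolist())
        known = set(self.labels["id"].tolist())
        missing = present - known
        if missing:
            raise ValueError(f"atlas labels {sorted(missing)} missing from label table")

    def label_id(self, name: str) -> int:
        row = self.labels[self.labels["name"] == name]
        if row.empty:
            raise KeyError(f"no ROI named {name!r}; have {list(self.labels['name'])}")
        return int(row["id"].iloc[0])

    def label_name(self, label: int) -> str:
        row = self.labels[self.labels["id"] == label]
        if row.empty:
            raise KeyError(f"no label id {label}")
        return str(row["name"].iloc[0])

    def brain_labels(self, near_skull: Optional[bool] = None) -> list[int]:
        tab = self.labels[self.labels["id"] >= FIRST_BRAIN_LABEL]
        if near_skull is not None:
            tab = tab[tab["near_skull"] == near_skull]
        return [int(i) for i in tab["id"]]

    def roi_centroid_world(self, label: int) -> tuple[float, float, float]:
        """World-coordinate centroid (mm) of one atlas label."""
        idx = np.argwhere(self.atlas.data == label)
        if idx.size == 0:
            raise KeyError(f"label {label} not present in atlas")
        c = idx.mean(axis=0)
        return tuple(self.atlas.origin[i] + c[i] * self.atlas.spacing[i] for i in range(3))


def generate_phantom(
    seed: int,
    grid: tuple[int, int, int] = (128, 128, 16),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    n_rois: int = 8,
) -> PhantomBundle:
    """Build a seeded brain-like phantom.

    The atlas geometry (shells and ROI partition) depends only on the grid;
    the seed drives the per-ROI activity perturbations, so two seeds share
    anatomy but differ in regional uptake — the stand-in for a patient
    cohort on a common template.
    """
    nx, ny, nz = grid
    if nx < 32 or ny < 32:
        raise ValueError(f"in-plane grid must be at least 32 voxels, got {grid}")
    if nz < 4:
        raise ValueError(f"need at least 4 slices, got nz={nz}")
    if n_rois < 4:
        raise ValueError(f"need n_rois >= 4, got {n_rois}")
    dx, dy, dz = (float(s) for s in spacing)

    r_max = min(nx * dx, ny * dy) / 2.0
    r_head = 0.92 * r_max
    r_skull_out = r_head - SCALP_THICKNESS_MM
    r_skull_in = r_skull_out - SKULL_THICKNESS_MM
    if r_skull_in < 5.0 * max(dx, dy):
        raise ValueError(
            f"grid {grid} at spacing {spacing} is too small to contain scalp, "
            f"skull and brain shells (inner brain radius {r_skull_in:.1f} mm)"
        )

    origin = (0.0, 0.0, 0.0)
    cx = dx * (nx - 1) / 2.0
    cy = dy * (ny - 1) / 2.0
    xs = dx * np.arange(nx)[:, None] - cx
    ys = dy * np.arange(ny)[None, :] - cy
    r2d = np.hypot(xs, ys)
    theta = np.mod(np.arctan2(ys, xs), 2 * np.pi)

    atlas2d = np.zeros((nx, ny), dtype=np.int32)
    atlas2d[r2d < r_head] = LABEL_SCALP
    atlas2d[r2d < r_skull_out] = LABEL_SKULL
    brain = r2d < r_skull_in

    n_cortical = (n_rois + 1) // 2
    n_deep = n_rois - n_cortical
    r_deep = 0.45 * r_skull_in

    cortical = brain & (r2d >= r_deep)
    deep = brain & (r2d < r_deep)
    sector_c = np.floor(theta / (2 * np.pi) * n_cortical).astype(np.int32)
    sector_c = np.clip(sector_c, 0, n_cortical - 1)
    # offset deep sectors by half a wedge so deep/cortical borders don't align
    sector_d = np.floor(np.mod(theta + np.pi / n_deep, 2 * np.pi) / (2 * np.pi) * n_deep)
    sector_d = np.clip(sector_d.astype(np.int32), 0, n_deep - 1)
    atlas2d[cortical] = FIRST_BRAIN_LABEL + sector_c[cortical]
    atlas2d[deep] = FIRST_BRAIN_LABEL + n_cortical + sector_d[deep]

    atlas3d = np.repeat(atlas2d[:, :, None], nz, axis=2)

    rows = [
        {"id": LABEL_AIR, "name": "air", "near_skull": False},
        {"id": LABEL_SCALP, "name": "scalp", "near_skull": True},
        {"id": LABEL_SKULL, "name": "skull", "near_skull": True},
    ]
    for k in range(n_cortical):
        name = _CORTICAL_NAMES[k % len(_CORTICAL_NAMES)]
        if k >= len(_CORTICAL_NAMES):
            name = f"{name}_{k // len(_CORTICAL_NAMES) + 1}"
        rows.append({"id": FIRST_BRAIN_LABEL + k, "name": name, "near_skull": True})
    for k in range(n_deep):
        name = _DEEP_NAMES[k % len(_DEEP_NAMES)]
        if k >= len(_DEEP_NAMES):
            name = f"{name}_{k // len(_DEEP_NAMES) + 1}"
        rows.append(
            {"id": FIRST_BRAIN_LABEL + n_cortical + k, "name": name, "near_skull": False}
        )
    labels = pd.DataFrame(rows, columns=["id", "name", "near_skull"])

    mu = np.zeros((nx, ny, nz), dtype=np.float64)
    mu[atlas3d == LABEL_SCALP] = MU_SOFT
    mu[atlas3d == LABEL_SKULL] = MU_BONE
    mu[atlas3d >= FIRST_BRAIN_LABEL] = MU_SOFT

    rng = np.random.default_rng(seed)
    activity = np.zeros((nx, ny, nz), dtype=np.float64)
    activity[atlas3d == LABEL_SCALP] = SCALP_ACTIVITY_FRACTION * BACKGROUND_ACTIVITY
    for k in range(n_rois):
        lab = FIRST_BRAIN_LABEL + k
        perturb = 1.0 + rng.uniform(-0.10, 0.10)
        activity[atlas3d == lab] = BACKGROUND_ACTIVITY * perturb

    return PhantomBundle(
        activity=VoxelVolume(activity, spacing, origin),
        atlas=VoxelVolume(atlas3d, spacing, origin),
        labels=labels,
        mu_ct=VoxelVolume(mu, spacing, origin),
        seed=int(seed),
    )


def derive_mrac(
    mu_ct: VoxelVolume,
    atlas: VoxelVolume,
    spec: MracVariantSpec,
    seed: int = 0,
) -> VoxelVolume:
    """Apply one MRAC-style degradation to the ground-truth μ-map."""
    if not mu_ct.same_grid(atlas):
        raise ValueError("mu_ct and atlas must be on the same grid")
    skull = atlas.data == LABEL_SKULL
    mu = mu_ct.data.astype(np.float64).copy()
    p = spec.parameters

    if spec.name == "CTAC":
        pass
    elif spec.name == "DIXON":
        mu[skull] = MU_SOFT
    elif spec.name == "DIXONBONE":
        scale = float(p.get("bone_scale", 0.95))
        nvox = int(p.get("erosion_voxels", 1))
        kept = skull
        if nvox > 0:
            # in-plane erosion: the bone model's mismatch is transaxial
            struct = np.zeros((3, 3, 1), dtype=bool)
            struct[1, :, 0] = True
            struct[:, 1, 0] = True
            kept = ndimage.binary_erosion(skull, structure=struct, iterations=nvox)
        mu[skull & ~kept] = MU_SOFT
        mu[kept] = scale * mu_ct.data[kept]
    elif spec.name == "UTE":
        bone_mu = float(p.get("bone_mu", MU_BONE_UTE))
        frac = float(p.get("misclassification_fraction", 0.2))
        mu[mu > 0] = MU_SOFT          # whole head a single soft class
        mu[skull] = bone_mu           # plus one bone class for the skull
        struct = np.zeros((3, 3, 1), dtype=bool)
        struct[1, :, 0] = True
        struct[:, 1, 0] = True
        inner = skull & ~ndimage.binary_erosion(skull, structure=struct)
        outer = ndimage.binary_dilation(skull, structure=struct) & ~skull & (mu_ct.data > 0)
        rng = np.random.default_rng(seed)
        for layer, flipped_to in ((inner, MU_SOFT), (outer, bone_mu)):
            idx = np.flatnonzero(layer)
            n_flip = int(round(frac * idx.size))
            if n_flip:
                chosen = rng.choice(idx, size=n_flip, replace=False)
                mu.flat[chosen] = flipped_to
    elif spec.name == "DLDIXON":
        sigma = float(p.get("noise_sigma_fraction", 0.01)) * MU_SOFT
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, size=mu.shape)
        mu = np.clip(mu + noise * (mu > 0), 0.0, None)
    else:  # pragma: no cover - MracVariantSpec already validates
        raise ValueError(f"unknown variant {spec.name}")

    return mu_ct.copy_with(np.clip(mu, 0.0, None))


def rasterize_sphere(
    grid_like: VoxelVolume,
    center: tuple[float, float, float],
    radius: float,
    supersample: int = 1,
) -> VoxelVolume:
    """Rasterize a sphere onto the grid of ``grid_like``.

    With ``supersample=1`` (default) the result is a binary voxel-center
    inclusion mask.  ``supersample=k`` returns fractional occupancy from a
    k×k×k subdivision of each voxel — useful for building smooth-edged
    analytic objects such as uniform discs for projector validation.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    out = np.zeros(grid_like.shape, dtype=np.float64 if supersample > 1 else np.uint8)
    axes = []
    for ax in range(3):
        centers = grid_like.voxel_centers(ax) - center[ax]
        if supersample > 1:
            sub = (np.arange(supersample) + 0.5) / supersample - 0.5
            centers = centers[:, None] + sub[None, :] * grid_like.spacing[ax]
        axes.append(centers)
    if supersample == 1:
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        out[d2 <= radius**2] = 1
    else:
        r2 = radius**2
        # accumulate sub-voxel hits; memory kept modest by looping z
        x2 = axes[0] ** 2  # (nx, k)
        y2 = axes[1] ** 2
        for iz in range(grid_like.shape[2]):
            z2 = axes[2][iz] ** 2  # (k,)
            d2 = (
                x2[:, None, :, None, None]
                + y2[None, :, None, :, None]
                + z2[None, None, None, None, :]
            )
            out[:, :, iz] = (d2 <= r2).mean(axis=(2, 3, 4))
    if not np.any(out):
        warnings.warn(
            f"sphere at {center} with radius {radius} mm lies entirely outside the grid",
            stacklevel=2,
        )
    return grid_like.copy_with(out)


def rasterize_disc(
    grid_like: VoxelVolume,
    center_xy: tuple[float, float],
    radius: float,
    supersample: int = 4,
) -> VoxelVolume:
    """Rasterize a z-aligned solid cylinder (disc in every slice).

    Fractional edge occupancy via in-plane supersampling; the analytic
    object of choice for chord-length and ACF closed-form checks.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    nx, ny, nz = grid_like.shape
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5 if supersample > 1 else np.zeros(1)
    x = grid_like.voxel_centers(0) - center_xy[0]
    y = grid_like.voxel_centers(1) - center_xy[1]
    xx = (x[:, None] + sub[None, :] * grid_like.spacing[0]) ** 2
    yy = (y[:, None] + sub[None, :] * grid_like.spacing[1]) ** 2
    d2 = xx[:, None, :, None] + yy[None, :, None, :]
    occ = (d2 <= radius**2).mean(axis=(2, 3))
    return grid_like.copy_with(np.repeat(occ[:, :, None], nz, axis=2))
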