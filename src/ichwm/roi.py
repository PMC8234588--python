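"""Lesion segmentation and spherical region-of-interest construction.

The analysis compartments are built from two geometric objects: a voxelised
lesion (hematoma) mask segmented from the b=0 image, and a constant-radius
analysis sphere centered on the lesion centroid with a mirror-image
counterpart in the opposite hemisphere. The sphere must never cross the
midsagittal plane — taken as the geometric center plane of the first
(left–right) voxel axis — so that the contralateral copy samples strictly
unaffected tissue; tangency to the plane is allowed.

All coordinates are world millimetres, voxel centers at ``index × spacing``
with 0-based indices and no affine rotation (identity orientation is
required of all inputs). A voxel belongs to a sphere iff its *center* lies
within the radius, which makes every volume in the pipeline
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dti import ScalarMap

logger = logging.getLogger(__name__)


class MidlineError(ValueError):
    """Sphere crosses the midsagittal plane."""


class LesionOverflowError(ValueError):
    """Lesion cannot be enclosed by a sphere within the allowed radius band."""


@dataclass(frozen=True)
class Grid:
    """Voxel lattice: shape plus spacing in mm (identity orientation)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)

    def __post_init__(self):
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be 3 positive ints")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @classmethod
    def of_map(cls, m: ScalarMap) -> "Grid":
        return cls(tuple(m.data.shape), m.voxel_spacing)

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def midplane_x_mm(self) -> float:
        return float(self.extent_mm[0] / 2.0)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def coords_mm(self):
        ax = [np.arange(n) * s for n, s in zip(self.shape, self.spacing)]
        return np.meshgrid(*ax, indexing="ij")


@dataclass(frozen=True)
class SphericalROI:
    """Analysis sphere: center and radius in mm plus its hemisphere label."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    side: str = "ipsilateral"     # "ipsilateral" | "contralateral"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        if self.side not in ("ipsilateral", "contralateral"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class LesionMask:
    """Voxelised hematoma segmentation."""

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("lesion mask must be 3D")

    @property
    def volume_ml(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return float(self.mask.sum()) * sx * sy * sz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MidlineCheck:
    passed: bool
    margin_mm: float   # distance from sphere surface to the midplane; < 0 = crossing


def segment_lesion(b0_map: ScalarMap, threshold_fraction: float = 0.5,
                   min_component_ml: float = 0.3) -> LesionMask:
    """Segment the hematoma as the hypointense blob on the b=0 image.

    Voxels darker than ``(1 − threshold_fraction) ×`` the robust background
    level (median of finite positive intensities) are candidates; the
    largest 26-connected component is kept if it reaches
    ``min_component_ml``, then closed morphologically. An empty mask — no
    lesion found — is a valid result, not an error.
    """
    data = np.asarray(b0_map.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("b0 map must be 3D")
    finite = np.isfinite(data) & (data > 0)
    if not finite.any():
        raise ValueError("b0 map has no positive finite voxels")
    background = float(np.median(data[finite]))
    candidates = finite & (data < (1.0 - threshold_fraction) * background)

    empty = LesionMask(np.zeros(data.shape, bool), b0_map.voxel_spacing)
    if not candidates.any():
        return empty

    labels, n = ndimage.label(candidates, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    sx, sy, sz = b0_map.voxel_spacing
    if sizes[largest - 1] * sx * sy * sz / 1000.0 < min_component_ml:
        return empty
    mask = labels == largest
    mask = ndimage.binary_closing(mask, structure=ndimage.generate_binary_structure(3, 1))
    return LesionMask(mask, b0_map.voxel_spacing)


def check_midline(roi: SphericalROI, grid: Grid) -> MidlineCheck:
    """No-midline-crossing rule: fails iff |center_x − midplane_x| < radius.

    The margin is signed (mm of clearance; negative = overlap); tangency
    (margin exactly 0) passes.
    """
    margin = abs(roi.center_mm[0] - grid.midplane_x_mm) - roi.radius_mm
    return MidlineCheck(passed=margin >= 0.0, margin_mm=float(margin))


def place_ipsilateral_sphere(lesion: LesionMask, grid: Grid,
                             radius_band_mm: tuple[float, float] = (20.0, 25.0),
                             center_mm: tuple[float, float, float] | None = None) -> SphericalROI:
    """Center the analysis sphere on the lesion centroid and size it to enclose it.

    The radius starts at the lower edge of the band and is escalated just
    enough to contain every lesion voxel center; a lesion needing more than
    the band maximum raises `LesionOverflowError` with the overflow, and a
    sphere reaching across the midline raises `MidlineError`. A manual
    ``center_mm`` overrides the centroid.
    """
    if lesion.n_voxels == 0:
        raise ValueError("cannot place a sphere on an empty lesion mask")
    idx = np.argwhere(lesion.mask)
    coords = idx * np.asarray(lesion.voxel_spacing)
    center = tuple(coords.mean(axis=0)) if center_mm is None else tuple(center_mm)

    needed = float(np.linalg.norm(coords - np.asarray(center), axis=1).max())
    lo, hi = radius_band_mm
    radius = max(lo, needed)
    if radius > hi:
        raise LesionOverflowError(
            f"lesion requires a {needed:.1f} mm sphere; allowed band is "
            f"[{lo}, {hi}] mm (overflow {needed - hi:.1f} mm)"
        )
    roi = SphericalROI(center, radius, side="ipsilateral")
    chk = check_midline(roi, grid)
    if not chk.passed:
        raise MidlineError(
            f"ipsilateral sphere (center x {center[0]:.1f} mm, radius {radius:.1f} mm) "
            f"crosses the midline by {-chk.margin_mm:.1f} mm"
        )
    return roi


def mirror_sphere(roi: SphericalROI, grid: Grid) -> SphericalROI:
    """Reflect the sphere across the midsagittal plane (x → 2·x_mid − x).

    The radius is preserved and the side label flipped; a reflected sphere
    extending beyond the voxel grid is an error.
    """
    cx = 2.0 * grid.midplane_x_mm - roi.center_mm[0]
    center = (cx, roi.center_mm[1], roi.center_mm[2])
    lo = np.asarray(center) - roi.radius_mm
    hi = np.asarray(center) + roi.radius_mm
    if np.any(lo < 0) or np.any(hi > grid.extent_mm):
        raise ValueError("mirrored sphere leaves the voxel grid")
    side = "contralateral" if roi.side == "ipsilateral" else "ipsilateral"
    return SphericalROI(center, roi.radius_mm, side=side)


def sphere_voxel_mask(roi: SphericalROI, grid: Grid) -> tuple[np.ndarray, float]:
    """Voxelise the sphere: a voxel is included iff its center is within radius."""
    xx, yy, zz = grid.coords_mm()
    cx, cy, cz = roi.center_mm
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
    mask = d2 <= roi.radius_mm ** 2
    return mask, float(mask.sum()) * grid.voxel_volume_ml
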