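"""Seed-based region growing, compartment labeling and joint-surface extraction.

The growth plate is non-mineralized cartilage, so it appears as a
low-intensity band between the two mineralized plates (epiphysis on the
joint side, metaphysis on the shaft side).  Mineralized tissue is segmented
by region growing from seed voxels within a gray-value tolerance interval;
the growth-plate band is then located as the z-interval where the
mineralized cross-sectional area is minimal, and everything is labeled
relative to that band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume3D

# Tissue labels.  Mineralized voxels inside the band are the bridge
# candidates and keep bone material downstream.
BACKGROUND = 0
EPIPHYSIS = 1
METAPHYSIS = 2
GROWTH_PLATE = 3
BRIDGE = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    EPIPHYSIS: "epiphysis",
    METAPHYSIS: "metaphysis",
    GROWTH_PLATE: "growth_plate",
    BRIDGE: "bridge",
}


class SegmentationError(ValueError):
    pass


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Neighborhood footprint: 6 = faces only, 26 = faces+edges+corners."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise SegmentationError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass(frozen=True)
class RegionGrowParams:
    """Seeds, closed gray tolerance interval [lo, hi], and connectivity.

    The default 26-connectivity keeps thin oblique bridges in one piece;
    face connectivity (6) would fragment them.
    """

    seeds: tuple
    tolerance: tuple
    connectivity: int = 26

    def __post_init__(self) -> None:
        lo, hi = self.tolerance
        if lo > hi:
            raise SegmentationError(f"tolerance interval reversed: [{lo}, {hi}]")
        connectivity_structure(self.connectivity)


@dataclass
class BinaryMask:
    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise SegmentationError("mask must be 3D")


@dataclass
class LabeledVolume:
    """Per-voxel tissue labels plus the growth-plate band.

    ``gp_band = (z_lo, z_hi)`` is the inclusive voxel z-interval of the
    growth-plate gap.  Epiphysis voxels have z > z_hi, metaphysis voxels
    z < z_lo (+z points toward the joint surface); the five labels
    partition the volume.
    """

    labels: np.ndarray
    gp_band: tuple
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        z_lo, z_hi = self.gp_band
        if not (0 <= z_lo <= z_hi < self.labels.shape[2]):
            raise SegmentationError(f"gp_band {self.gp_band} outside volume z-range")


@dataclass
class JointSurface:
    """Topmost mineralized surface of the tibial plateau.

    ``height_map[x, y]`` is the physical z (μm, voxel-center) of the top
    mineralized voxel of the column; defined exactly where ``footprint`` is
    True.  ``height_vox`` keeps the voxel-index version for convenience.
    """

    height_map: np.ndarray
    footprint: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def height_vox(self) -> np.ndarray:
        return (self.height_map - self.origin[2]) / self.voxel_size


# ---------------------------------------------------------------------------


def region_grow(vol: Volume3D, params: RegionGrowParams) -> BinaryMask:
    """Select all voxels connected to a seed with gray value in [lo, hi].

    The result is exactly the union of connected components of the
    thresholded set that contain at least one seed; deterministic.
    """
    lo, hi = params.tolerance
    for s in params.seeds:
        s = tuple(int(v) for v in s)
        if any(c < 0 or c >= n for c, n in zip(s, vol.shape)):
            raise SegmentationError(f"seed {s} outside volume bounds {vol.shape}")
        g = vol.data[s]
        if not (lo <= g <= hi):
            raise SegmentationError(
                f"seed {s} has gray value {g}, outside tolerance [{lo}, {hi}]"
            )
    inside = (vol.data >= lo) & (vol.data <= hi)
    comp, _ = ndimage.label(inside, structure=connectivity_structure(params.connectivity))
    keep = {int(comp[tuple(int(v) for v in s)]) for s in params.seeds}
    keep.discard(0)
    mask = np.isin(comp, sorted(keep))
    return BinaryMask(mask, vol.voxel_size)


def _area_profile(bone: np.ndarray) -> np.ndarray:
    return bone.sum(axis=(0, 1)).astype(float)


def locate_gp_band(bone_mask: BinaryMask, smooth: int = 5, rel_height: float = 0.1):
    """Find the growth-plate gap as the z-interval of minimal mineralized area.

    The per-slice mineralized area is smoothed with a ``smooth``-slice
    moving average; the band is the contiguous interval around the interior
    argmin whose raw area stays below ``min + rel_height * (peak - min)``,
    where ``peak`` is the smaller of the two flanking maxima.  Thin bridges
    crossing the gap occupy far less than 10% of a plate cross-section, so
    they do not close the band.
    """
    area = _area_profile(bone_mask.data)
    nz = len(area)
    support = np.nonzero(area > 0)[0]
    if len(support) == 0:
        raise SegmentationError("bone mask is empty")
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(area, kernel, mode="same")

    z0, z1 = support[0], support[-1]
    interior = np.arange(z0 + 1, z1)
    if len(interior) == 0:
        raise SegmentationError("no interior slices; cannot locate growth-plate band")
    zmin = interior[np.argmin(smoothed[interior])]
    peak_below = area[z0:zmin + 1].max()
    peak_above = area[zmin:z1 + 1].max()
    a_min = area[zmin]
    peak = min(peak_below, peak_above)
    if not (a_min <= 0.5 * peak):
        raise SegmentationError(
            "mineralized area profile has no clear interior minimum (monotone or "
            "solid object); pass gp_band_hint explicitly"
        )
    thr = a_min + rel_height * (peak - a_min)
    lo = zmin
    while lo - 1 > z0 and area[lo - 1] <= thr:
        lo -= 1
    hi = zmin
    while hi + 1 < z1 and area[hi + 1] <= thr:
        hi += 1
    return int(lo), int(hi)


def label_compartments(
    bone_mask: BinaryMask,
    gp_band_hint: tuple | None = None,
    origin: np.ndarray | None = None,
) -> LabeledVolume:
    """Label epiphysis/metaphysis/growth plate around the growth-plate band.

    Mineralized voxels above the band become epiphysis, below it
    metaphysis, inside it bridge candidates; non-mineralized voxels inside
    the band are growth-plate cartilage.  ``gp_band_hint`` (inclusive voxel
    z-interval) is honored verbatim when given.
    """
    bone = bone_mask.data
    if not bone.any():
        raise SegmentationError("bone mask is empty")
    if gp_band_hint is not None:
        z_lo, z_hi = int(gp_band_hint[0]), int(gp_band_hint[1])
    else:
        z_lo, z_hi = locate_gp_band(bone_mask)

    labels = np.zeros(bone.shape, dtype=np.uint8)
    z = np.arange(bone.shape[2])[None, None, :]
    labels[bone & (z > z_hi)] = EPIPHYSIS
    labels[bone & (z < z_lo)] = METAPHYSIS
    in_band = (z >= z_lo) & (z <= z_hi)
    labels[bone & in_band] = BRIDGE
    labels[(~bone) & in_band] = GROWTH_PLATE
    org = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    return LabeledVolume(labels, (z_lo, z_hi), bone_mask.voxel_size, origin=org)


def extract_joint_surface(labeled: LabeledVolume, bone_mask: BinaryMask) -> JointSurface:
    """Height map of the topmost mineralized voxel over the plateau footprint.

    The footprint is the set of (x, y) columns containing at least one
    epiphyseal voxel; within it the height is the maximum z of mineralized
    voxels in the column, converted to physical μm (voxel-center).  Adding
    mineralized voxels strictly below the current surface leaves the map
    unchanged.
    """
    epi = labeled.labels == EPIPHYSIS
    if not epi.any():
        raise SegmentationError("epiphysis label is empty; cannot extract joint surface")
    footprint = epi.any(axis=2)
    bone = bone_mask.data
    nz = bone.shape[2]
    # argmax over reversed z gives the topmost True per column
    has_bone = bone.any(axis=2)
    top = nz - 1 - np.argmax(bone[:, :, ::-1], axis=2)
    height = np.full(footprint.shape, np.nan)
    valid = footprint & has_bone
    height[valid] = labeled.origin[2] + labeled.voxel_size * top[valid]
    return JointSurface(height, valid, labeled.voxel_size, origin=labeled.origin)
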