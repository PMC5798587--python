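"""Detection and morphometry of bony bridges crossing the growth plate.

A bridge is a mineralized connected component, restricted to the
growth-plate band, that is adjacent to both the epiphyseal and the
metaphyseal bone — i.e. it crosses the entire width of the plate.
Components below a minimum voxel volume (default 125 voxels) are discarded
to suppress partial-volume artifacts, and each surviving bridge is reduced
to a single center point via its medial-axis skeleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segmentation import (
    EPIPHYSIS,
    METAPHYSIS,
    BinaryMask,
    LabeledVolume,
    SegmentationError,
    connectivity_structure,
)

log = logging.getLogger(__name__)


@dataclass
class Bridge:
    """One spanning component: voxel morphometry plus a center point (μm)."""

    id: int
    voxel_count: int
    volume_um3: float
    center: np.ndarray
    bbox: tuple  # ((x0, x1), (y0, y1), (z0, z1)) inclusive voxel bounds
    touches: dict
    voxels: np.ndarray = field(repr=False, default=None)  # (n, 3) voxel indices

    @property
    def spans(self) -> bool:
        return bool(self.touches["epiphysis"] and self.touches["metaphysis"])


@dataclass(frozen=True)
class BridgeFilterParams:
    """Minimum component volume; components smaller than ``min_voxels`` are
    dropped, so a 125-voxel component is retained under the default."""

    min_voxels: int = 125

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


@dataclass
class BridgeSet:
    bridges: list
    voxel_size: float
    provenance: dict = field(default_factory=dict)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __len__(self) -> int:
        return len(self.bridges)

    def __iter__(self):
        return iter(self.bridges)

    def to_records(self) -> list:
        return [
            {
                "id": b.id,
                "voxel_count": b.voxel_count,
                "volume_um3": b.volume_um3,
                "cx_um": float(b.center[0]),
                "cy_um": float(b.center[1]),
                "cz_um": float(b.center[2]),
                "touches_epi": b.touches["epiphysis"],
                "touches_met": b.touches["metaphysis"],
            }
            for b in self.bridges
        ]


def find_candidate_bridges(
    labeled: LabeledVolume,
    bone_mask: BinaryMask,
    connectivity: int = 26,
    seeds: list | None = None,
) -> BridgeSet:
    """Connected mineralized components in the band that touch both plates.

    Components adjacent (under ``connectivity``) to only one of the two
    compartments — spurs — are excluded.  Ids are deterministic, ordered by
    the (min z, min y, min x) corner of the bounding box.  ``seeds``, if
    given, restricts the result to components containing one of the given
    voxel indices (the manual-identification mode).
    """
    z_lo, z_hi = labeled.gp_band
    band = np.zeros(labeled.labels.shape, dtype=bool)
    band[:, :, z_lo:z_hi + 1] = True
    if not band.any():
        raise SegmentationError("growth-plate band is empty")
    in_band_bone = bone_mask.data & band

    structure = connectivity_structure(connectivity)
    comp, n = ndimage.label(in_band_bone, structure=structure)

    epi = labeled.labels == EPIPHYSIS
    met = labeled.labels == METAPHYSIS
    if not epi.any() or not met.any():
        raise SegmentationError("labeled volume needs non-empty epiphysis and metaphysis")
    # A component touches a compartment iff it meets the compartment dilated
    # by the connectivity structure.
    near_epi = ndimage.binary_dilation(epi, structure=structure)
    near_met = ndimage.binary_dilation(met, structure=structure)

    touches_epi = np.zeros(n + 1, dtype=bool)
    touches_met = np.zeros(n + 1, dtype=bool)
    ids_epi = np.unique(comp[near_epi])
    ids_met = np.unique(comp[near_met])
    touches_epi[ids_epi] = True
    touches_met[ids_met] = True

    allowed = None
    if seeds is not None:
        allowed = {int(comp[tuple(int(v) for v in s)]) for s in seeds}
        allowed.discard(0)

    vs = labeled.voxel_size
    objects = ndimage.find_objects(comp)
    entries = []
    for lab in range(1, n + 1):
        if not (touches_epi[lab] and touches_met[lab]):
            continue
        if allowed is not None and lab not in allowed:
            continue
        sl = objects[lab - 1]
        sub = comp[sl] == lab
        vox = np.argwhere(sub) + np.array([s.start for s in sl])
        bbox = tuple((s.start, s.stop - 1) for s in sl)
        centroid_vox = vox.mean(axis=0)
        center = labeled.origin + vs * centroid_vox
        entries.append((
            (bbox[2][0], bbox[1][0], bbox[0][0]),  # order key: (min z, min y, min x)
            Bridge(
                id=-1,
                voxel_count=int(len(vox)),
                volume_um3=float(len(vox)) * vs**3,
                center=center,
                bbox=bbox,
                touches={"epiphysis": True, "metaphysis": True},
                voxels=vox,
            ),
        ))
    entries.sort(key=lambda e: e[0])
    bridges = []
    for i, (_, b) in enumerate(entries):
        b.id = i + 1
        bridges.append(b)
    return BridgeSet(
        bridges,
        vs,
        provenance={"connectivity": connectivity, "gp_band": [int(z_lo), int(z_hi)],
                    "seeded": seeds is not None},
        origin=labeled.origin,
    )


def filter_by_volume(bs: BridgeSet, params: BridgeFilterParams = BridgeFilterParams()) -> BridgeSet:
    """Drop bridges smaller than ``min_voxels``; order and ids are kept."""
    kept = [b for b in bs.bridges if b.voxel_count >= params.min_voxels]
    prov = dict(bs.provenance, min_voxels=params.min_voxels)
    return BridgeSet(kept, bs.voxel_size, provenance=prov, origin=bs.origin)


def _skeleton_center(b: Bridge, voxel_size: float, origin: np.ndarray) -> np.ndarray:
    """Skeleton voxel nearest the component centroid (ties: smallest (z,y,x)).

    The skeleton is the Euclidean distance-transform medial axis: voxels
    whose distance to the component boundary is maximal within their 26-
    neighborhood (centers of maximal inscribed balls).  Unlike iterative
    thinning, this keeps the full axis of short, thick components instead
    of collapsing them toward one end, and it guarantees the reported
    center lies inside the component even for bent bridges, where the raw
    centroid can fall outside the mineralized tissue.
    """
    vox = b.voxels
    lo = vox.min(axis=0)
    shape = vox.max(axis=0) - lo + 1
    sub = np.zeros(shape + 2, dtype=bool)  # 1-voxel pad so the boundary is seen
    sub[tuple((vox - lo + 1).T)] = True
    dt = ndimage.distance_transform_edt(sub)
    # half-voxel plateau tolerance: rasterization jitters the axis distance
    # by up to ~0.5 voxel, which would otherwise thin the ridge to a few
    # isolated bumps on tilted cylinders
    ridge = sub & (dt >= ndimage.maximum_filter(dt, size=3) - 0.5)
    skel_vox = np.argwhere(ridge) - 1 + lo
    if len(skel_vox) == 0:
        log.info("bridge %d: empty skeleton, falling back to nearest component voxel", b.id)
        skel_vox = vox
    centroid = vox.mean(axis=0)
    d2 = ((skel_vox - centroid) ** 2).sum(axis=1)
    best = d2.min()
    cand = skel_vox[d2 <= best + 1e-12]
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))  # sort by (z, y, x)
    chosen = cand[order[0]].astype(float)
    # sub-voxel refinement: average the ridge voxels adjacent to the chosen
    # one, accepted only if the refined point still falls inside the
    # component (preserves the inside-the-bridge guarantee at bends)
    near = skel_vox[np.abs(skel_vox - chosen).max(axis=1) <= 1]
    refined = near.mean(axis=0)
    vox_set = {tuple(v) for v in vox}
    if tuple(np.rint(refined).astype(int)) in vox_set:
        chosen = refined
    return origin + voxel_size * chosen


def bridge_centers(
    bs: BridgeSet,
    method: str = "skeleton",
    origin: np.ndarray | None = None,
) -> BridgeSet:
    """Populate one center point per bridge.

    ``skeleton``: medial-axis skeleton voxel nearest the centroid (always
    inside the component).  ``centroid``: arithmetic mean of voxel centers,
    which may fall outside a bent component.
    """
    if method not in ("skeleton", "centroid"):
        raise ValueError(f"unknown center method {method!r}")
    org = bs.origin if origin is None else np.asarray(origin, dtype=float)
    out = []
    for b in bs.bridges:
        if b.voxels is None or len(b.voxels) == 0:
            raise ValueError(f"bridge {b.id} carries no voxels")
        if method == "centroid" or len(b.voxels) == 1:
            center = org + bs.voxel_size * b.voxels.mean(axis=0)
        else:
            center = _skeleton_center(b, bs.voxel_size, org)
        out.append(replace(b, center=center))
    prov = dict(bs.provenance, center_method=method)
    return BridgeSet(out, bs.voxel_size, provenance=prov, origin=bs.origin)
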