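"""Projection of bridge centers onto the joint surface and areal number density.

Each bridge center is carried along a straight +z line onto the tibial
plateau; the areal number density N_A is then the number of projected
bridges per square window (default 256 μm × 256 μm), tiled over the
surface footprint with half-open cells so every point is counted exactly
once.  Each bridge inherits the N_A of its containing window for the
surface overlay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .bridges import BridgeSet
from .segmentation import JointSurface

PROJECTED = "projected"
MISSED = "missed"


@dataclass
class ProjectedPoint:
    bridge_id: int
    surface_xy: tuple
    surface_z: float | None
    status: str


@dataclass(frozen=True)
class DensityParams:
    """Square window side (μm) and the physical (x, y) anchor of the grid.

    ``grid_anchor=None`` anchors the grid at the minimum (x, y) corner of
    the surface footprint's bounding box — a deterministic choice recorded
    in provenance, since no anatomical grid registration is defined.
    """

    window_um: float = 256.0
    grid_anchor: tuple | None = None

    def __post_init__(self) -> None:
        if not (self.window_um > 0):
            raise ValueError("window_um must be positive")


@dataclass
class DensityMap:
    counts: np.ndarray           # (nx_win, ny_win) integer N_A per window
    anchor: np.ndarray           # physical (x, y) of window (0, 0) corner, μm
    window_um: float
    per_bridge_density: dict     # bridge_id -> N_A of its window
    point_windows: dict = field(default_factory=dict)  # bridge_id -> (m, n)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def window_centers(self):
        """Physical (x, y) centers of all windows, same grid shape as counts."""
        m = np.arange(self.counts.shape[0])
        n = np.arange(self.counts.shape[1])
        x = self.anchor[0] + (m + 0.5) * self.window_um
        y = self.anchor[1] + (n + 0.5) * self.window_um
        return np.meshgrid(x, y, indexing="ij")


def _bilinear_height(surface: JointSurface, xi: float, yi: float) -> float | None:
    """Bilinear height lookup at fractional column index; None off-footprint.

    Uses the footprint columns among the four neighbors with renormalized
    weights, so points near the footprint rim still project; returns None
    when no neighbor column is defined.
    """
    fp = surface.footprint
    nx, ny = fp.shape
    x0, y0 = int(np.floor(xi)), int(np.floor(yi))
    fx, fy = xi - x0, yi - y0
    wsum = 0.0
    hsum = 0.0
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            x, y = x0 + dx, y0 + dy
            w = wx * wy
            if w <= 0 or not (0 <= x < nx and 0 <= y < ny) or not fp[x, y]:
                continue
            wsum += w
            hsum += w * surface.height_map[x, y]
    if wsum == 0.0:
        return None
    return hsum / wsum


def project_to_surface(bs: BridgeSet, surface: JointSurface) -> list:
    """Project each bridge center along +z onto the joint surface.

    A center whose (x, y) column lies outside the plateau footprint is
    returned with ``status="missed"``; misses are reported, never silently
    dropped, but excluded from density.
    """
    points = []
    for b in bs.bridges:
        cx, cy = float(b.center[0]), float(b.center[1])
        xi = (cx - surface.origin[0]) / surface.voxel_size
        yi = (cy - surface.origin[1]) / surface.voxel_size
        h = _bilinear_height(surface, xi, yi)
        if h is None:
            points.append(ProjectedPoint(b.id, (cx, cy), None, MISSED))
        else:
            points.append(ProjectedPoint(b.id, (cx, cy), float(h), PROJECTED))
    return points


def areal_density(points: list, params: DensityParams = DensityParams(),
                  surface: JointSurface | None = None) -> DensityMap:
    """Windowed areal number density N_A of projected points.

    Cells are half-open squares [x0+m·w, x0+(m+1)·w) × [y0+n·w, y0+(n+1)·w),
    so Σ counts equals the number of projected points.  The anchor defaults
    to ``params.grid_anchor``, else the minimum (x, y) corner of the
    surface footprint, else the minimum point coordinate.
    """
    proj = [p for p in points if p.status == PROJECTED]
    w = params.window_um

    if params.grid_anchor is not None:
        anchor = np.asarray(params.grid_anchor, dtype=float)
    elif surface is not None and surface.footprint.any():
        idx = np.argwhere(surface.footprint)
        anchor = surface.origin[:2] + surface.voxel_size * idx.min(axis=0)
    elif proj:
        anchor = np.floor(np.array([[p.surface_xy[0], p.surface_xy[1]] for p in proj]).min(axis=0))
    else:
        anchor = np.zeros(2)

    if surface is not None and surface.footprint.any():
        idx = np.argwhere(surface.footprint)
        xy_max = surface.origin[:2] + surface.voxel_size * idx.max(axis=0)
    elif proj:
        xy_max = np.array([[p.surface_xy[0], p.surface_xy[1]] for p in proj]).max(axis=0)
    else:
        xy_max = anchor

    cells = {}
    for p in proj:
        m = int(np.floor((p.surface_xy[0] - anchor[0]) / w))
        n = int(np.floor((p.surface_xy[1] - anchor[1]) / w))
        cells[p.bridge_id] = (m, n)

    n_x = max(int(np.floor((xy_max[0] - anchor[0]) / w)) + 1, 1)
    n_y = max(int(np.floor((xy_max[1] - anchor[1]) / w)) + 1, 1)
    if cells:
        n_x = max(n_x, max(c[0] for c in cells.values()) + 1)
        n_y = max(n_y, max(c[1] for c in cells.values()) + 1)
        m_min = min(min(c[0] for c in cells.values()), 0)
        n_min = min(min(c[1] for c in cells.values()), 0)
    else:
        m_min = n_min = 0
    # allow points left/below the anchor by shifting the grid, keeping the
    # anchor's lattice
    if m_min < 0 or n_min < 0:
        anchor = anchor + w * np.array([m_min, n_min])
        cells = {k: (m - m_min, n - n_min) for k, (m, n) in cells.items()}
        n_x += -m_min
        n_y += -n_min

    counts = np.zeros((n_x, n_y), dtype=int)
    for m, n in cells.values():
        counts[m, n] += 1
    per_bridge = {bid: int(counts[mn]) for bid, mn in cells.items()}
    return DensityMap(counts, anchor, w, per_bridge, point_windows=cells)


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

def _density_image(dm: DensityMap, surface: JointSurface, colormap: str) -> np.ndarray:
    """RGB image (one pixel per surface column) of N_A over the footprint."""
    fp = surface.footprint
    nx, ny = fp.shape
    w = dm.window_um
    xi = surface.origin[0] + surface.voxel_size * np.arange(nx)
    yi = surface.origin[1] + surface.voxel_size * np.arange(ny)
    m = np.clip(np.floor((xi - dm.anchor[0]) / w).astype(int), 0, dm.counts.shape[0] - 1)
    n = np.clip(np.floor((yi - dm.anchor[1]) / w).astype(int), 0, dm.counts.shape[1] - 1)
    na = dm.counts[np.ix_(m, n)].astype(float)
    vmax = max(float(dm.counts.max()), 1.0)
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(na / vmax)
    img = (rgba[:, :, :3] * 255).astype(np.uint8)
    img[~fp] = (30, 30, 30)  # off-footprint background
    # image rows = y decreasing for a conventional orientation
    return img.transpose(1, 0, 2)[::-1]


def _write_surface_ply(path: Path, surface: JointSurface, dm: DensityMap,
                       colormap: str) -> None:
    """ASCII PLY of the joint surface, per-vertex color = N_A at the column."""
    fp = surface.footprint
    nx, ny = fp.shape
    vid = -np.ones((nx, ny), dtype=int)
    verts = []
    cols = []
    w = dm.window_um
    vmax = max(float(dm.counts.max()), 1.0)
    cmap = matplotlib.colormaps[colormap]
    for x in range(nx):
        for y in range(ny):
            if not fp[x, y]:
                continue
            vid[x, y] = len(verts)
            px = surface.origin[0] + surface.voxel_size * x
            py = surface.origin[1] + surface.voxel_size * y
            pz = surface.height_map[x, y]
            m = min(max(int(np.floor((px - dm.anchor[0]) / w)), 0), dm.counts.shape[0] - 1)
            n = min(max(int(np.floor((py - dm.anchor[1]) / w)), 0), dm.counts.shape[1] - 1)
            r, g, b, _ = cmap(dm.counts[m, n] / vmax)
            verts.append((px, py, pz))
            cols.append((int(r * 255), int(g * 255), int(b * 255)))
    faces = []
    for x in range(nx - 1):
        for y in range(ny - 1):
            q = [vid[x, y], vid[x + 1, y], vid[x + 1, y + 1], vid[x, y + 1]]
            if all(v >= 0 for v in q):
                faces.append((q[0], q[1], q[2]))
                faces.append((q[0], q[2], q[3]))
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(verts)}\n")
        f.write("property float x\nproperty float y\nproperty float z\n")
        f.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        f.write(f"element face {len(faces)}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for (px, py, pz), (r, g, b) in zip(verts, cols):
            f.write(f"{px:.3f} {py:.3f} {pz:.3f} {r} {g} {b}\n")
        for a, b_, c in faces:
            f.write(f"3 {a} {b_} {c}\n")


def render_overlay(dm: DensityMap, surface: JointSurface, out,
                   colormap: str = "viridis") -> dict:
    """Write the 2D N_A heat map (PNG) and the colored 3D surface (PLY).

    ``out`` is a path stem; ``<out>.png`` and ``<out>.ply`` are written.
    Output is deterministic for fixed input (PNG via Pillow, no timestamps).
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    img = _density_image(dm, surface, colormap)
    png = out.with_suffix(".png")
    Image.fromarray(img).save(png)
    ply = out.with_suffix(".ply")
    _write_surface_ply(ply, surface, dm, colormap)
    return {"png": png, "ply": ply, "colormap": colormap}
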