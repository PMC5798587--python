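"""Synthetic microCT-like phantoms with exact ground truth.

A phantom is two mineralized plates (metaphysis below, epiphysis above)
separated by a low-intensity growth-plate gap, crossed by a configurable
set of cylindrical bridges, with optional sinusoidal undulation of the
joint (top) surface and Gaussian gray-level noise.  Every geometric fact —
labels, per-bridge voxel volumes, bridge centers, the surface height map —
is recorded exactly at generation time, so each pipeline stage can be
validated against construction rather than against itself.

The gray-level model is deliberately simple (tissue means + Gaussian
noise): the analysis pipeline, not the scanner physics, is under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import BRIDGE, EPIPHYSIS, GROWTH_PLATE, METAPHYSIS
from .volume_io import Volume3D


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class BridgeCylinder:
    """One bridge: a disk of ``radius_vox`` swept across the gap, optionally
    sheared in x by ``tilt_deg`` (axis slope dx/dz = tan(tilt))."""

    center_xy: tuple
    radius_vox: float = 3.0
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_vox < 1:
            raise PhantomError(f"bridge radius must be >= 1 voxel, got {self.radius_vox}")
        if abs(self.tilt_deg) > 30:
            raise PhantomError("bridge tilt limited to 30 degrees")


@dataclass(frozen=True)
class GrayLevels:
    """Tissue gray means and noise; separations stay >= 4·noise_sd so that
    threshold segmentation is well-posed by construction."""

    bone_mean: float = 200.0
    cartilage_mean: float = 80.0
    background_mean: float = 20.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        gaps = (self.bone_mean - self.cartilage_mean, self.cartilage_mean - self.background_mean)
        if self.noise_sd > 0 and min(gaps) < 4 * self.noise_sd:
            raise PhantomError(
                f"gray separations {gaps} must be >= 4*noise_sd = {4 * self.noise_sd}"
            )


@dataclass(frozen=True)
class Undulation:
    amplitude_vox: float = 0.0
    period_vox: float = 32.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (96, 96, 48)
    voxel_size: float = 5.0            # μm, benchtop-scanner scale
    plate_thickness: tuple = (12, 12)  # (metaphysis, epiphysis) voxels
    gap_thickness: int = 10
    bridges: tuple = ()
    undulation: Undulation = Undulation()
    gray_levels: GrayLevels = GrayLevels()
    lateral_margin: int = 3            # background frame around the plates
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_thickness < 1:
            raise PhantomError("gap_thickness must be >= 1 voxel")
        met, epi = self.plate_thickness
        nz = self.shape[2]
        amp = self.undulation.amplitude_vox
        if met + self.gap_thickness + epi + math.ceil(amp) + 1 > nz:
            raise PhantomError("plates + gap + undulation do not fit in the z extent")

    @property
    def gp_band(self) -> tuple:
        met = self.plate_thickness[0]
        return (met, met + self.gap_thickness - 1)


@dataclass
class GroundTruth:
    """Exact construction record for a generated phantom."""

    labels: np.ndarray
    gp_band: tuple
    bridge_volumes: list          # in-band voxel count per bridge
    bridge_centers_vox: list      # axis point at the band's mid-z, voxel coords
    bridge_centers_um: list
    surface_height_vox: np.ndarray  # topmost epiphyseal voxel per column
    surface_footprint: np.ndarray
    voxel_size: float

    def surface_height_um(self) -> np.ndarray:
        return self.surface_height_vox * self.voxel_size


def _surface_top_vox(spec: PhantomSpec, x: np.ndarray) -> np.ndarray:
    """Top epiphyseal voxel index per x (undulation is a function of x)."""
    met, epi = spec.plate_thickness
    base = met + spec.gap_thickness + epi - 1
    amp, per = spec.undulation.amplitude_vox, spec.undulation.period_vox
    if amp == 0:
        return np.full_like(x, base)
    return np.rint(base + amp * np.sin(2 * np.pi * x / per)).astype(int)


def _bridge_voxels(spec: PhantomSpec, b: BridgeCylinder) -> np.ndarray:
    """Voxels of one bridge, spanning the gap plus one voxel into each plate."""
    nx, ny, _ = spec.shape
    z_lo, z_hi = spec.gp_band
    slope = math.tan(math.radians(b.tilt_deg))
    z_mid = (z_lo + z_hi) / 2.0
    out = []
    r2 = b.radius_vox**2
    r_ceil = int(math.ceil(b.radius_vox))
    for z in range(z_lo - 1, z_hi + 2):
        cx = b.center_xy[0] + slope * (z - z_mid)
        cy = b.center_xy[1]
        x0, x1 = int(math.floor(cx - r_ceil)), int(math.ceil(cx + r_ceil))
        y0, y1 = int(math.floor(cy - r_ceil)), int(math.ceil(cy + r_ceil))
        if x0 < 0 or y0 < 0 or x1 >= nx or y1 >= ny:
            raise PhantomError(f"bridge at {b.center_xy} leaves the volume at z={z}")
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r2
        for x, y in zip(X[inside], Y[inside]):
            out.append((x, y, z))
    return np.array(out, dtype=int)


def build_labels(spec: PhantomSpec):
    """Noiseless label volume plus per-bridge voxel lists."""
    nx, ny, nz = spec.shape
    met, epi = spec.plate_thickness
    z_lo, z_hi = spec.gp_band
    m = spec.lateral_margin
    labels = np.zeros(spec.shape, dtype=np.uint8)

    inx = np.zeros((nx, ny), dtype=bool)
    inx[m:nx - m if m else nx, m:ny - m if m else ny] = True

    z = np.arange(nz)[None, None, :]
    labels[(z < z_lo) & inx[:, :, None]] = METAPHYSIS
    labels[(z >= z_lo) & (z <= z_hi) & inx[:, :, None]] = GROWTH_PLATE

    top = _surface_top_vox(spec, np.arange(nx))
    epi_mask = (z > z_hi) & (z <= top[:, None, None]) & inx[:, :, None]
    labels[epi_mask] = EPIPHYSIS

    bridge_vox = []
    sets = []
    for i, b in enumerate(spec.bridges):
        vox = _bridge_voxels(spec, b)
        if not inx[vox[:, 0], vox[:, 1]].all():
            raise PhantomError(f"bridge {i} extends into the lateral margin")
        sets.append(set(map(tuple, vox)))
        bridge_vox.append(vox)
    # bridges must not overlap or touch (26-neighborhood), else they merge
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            near_j = sets[j] | {
                (x + dx, y + dy, zz + dz)
                for (x, y, zz) in sets[j]
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            }
            if sets[i] & near_j:
                raise PhantomError(f"bridges {i} and {j} overlap or touch")
    for vox in bridge_vox:
        in_band = (vox[:, 2] >= z_lo) & (vox[:, 2] <= z_hi)
        labels[tuple(vox[in_band].T)] = BRIDGE
    return labels, bridge_vox


def generate_phantom(spec: PhantomSpec):
    """Generate (Volume3D, GroundTruth); deterministic for a fixed seed."""
    labels, bridge_vox = build_labels(spec)
    z_lo, z_hi = spec.gp_band
    gl = spec.gray_levels

    means = np.array([gl.background_mean, gl.bone_mean, gl.bone_mean,
                      gl.cartilage_mean, gl.bone_mean])
    gray = means[labels].astype(np.float32)
    if gl.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, gl.noise_sd, size=gray.shape).astype(np.float32)

    z_mid = (z_lo + z_hi) / 2.0
    centers_vox = []
    volumes = []
    for b, vox in zip(spec.bridges, bridge_vox):
        in_band = (vox[:, 2] >= z_lo) & (vox[:, 2] <= z_hi)
        volumes.append(int(in_band.sum()))
        centers_vox.append(np.array([b.center_xy[0], b.center_xy[1], z_mid]))

    epi = labels == EPIPHYSIS
    footprint = epi.any(axis=2)
    nzz = labels.shape[2]
    mineral = np.isin(labels, (EPIPHYSIS, METAPHYSIS, BRIDGE))
    top = nzz - 1 - np.argmax(mineral[:, :, ::-1], axis=2)
    height_vox = np.where(footprint, top, -1)

    truth = GroundTruth(
        labels=labels,
        gp_band=(z_lo, z_hi),
        bridge_volumes=volumes,
        bridge_centers_vox=centers_vox,
        bridge_centers_um=[c * spec.voxel_size for c in centers_vox],
        surface_height_vox=height_vox,
        surface_footprint=footprint,
        voxel_size=spec.voxel_size,
    )
    return Volume3D(gray, spec.voxel_size), truth


def random_phantom_spec(
    n_bridges: int,
    seed: int,
    shape: tuple = (128, 128, 48),
    gap_thickness: int = 10,
    radius_range: tuple = (2.0, 4.0),
    max_tilt_deg: float = 20.0,
    undulation_amplitude: float = 2.0,
) -> PhantomSpec:
    """Random well-separated bridge layout on a jittered grid (seeded).

    Bridges are placed at jittered positions of a coarse grid with spacing
    large enough that no two can touch, even at maximum tilt and radius.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    gap = gap_thickness
    r_max = radius_range[1]
    reach = r_max + math.tan(math.radians(max_tilt_deg)) * (gap / 2 + 1)
    pitch = int(math.ceil(2 * reach + 3))
    margin = int(math.ceil(reach)) + 5
    xs = np.arange(margin, nx - margin, pitch)
    ys = np.arange(margin, ny - margin, pitch)
    sites = [(x, y) for x in xs for y in ys]
    if n_bridges > len(sites):
        raise PhantomError(f"cannot place {n_bridges} bridges in shape {shape}")
    chosen = rng.choice(len(sites), size=n_bridges, replace=False)
    bridges = []
    for idx in chosen:
        x, y = sites[idx]
        jx, jy = rng.uniform(-1.0, 1.0, 2)
        r = rng.uniform(*radius_range)
        tilt = rng.uniform(-max_tilt_deg, max_tilt_deg)
        bridges.append(BridgeCylinder((float(x + jx), float(y + jy)), float(r), float(tilt)))
    return PhantomSpec(
        shape=shape,
        gap_thickness=gap,
        bridges=tuple(bridges),
        undulation=Undulation(amplitude_vox=undulation_amplitude),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def sweep_bridge_volumes(base_spec: PhantomSpec, volumes: list):
    """Phantom whose spanning components have exactly the requested voxel counts.

    Each component is built by direct voxel placement, not cylinder
    rasterization: a one-voxel column through the full gap (so it spans),
    grown voxel-by-voxel inside the band in a deterministic nearest-first
    order until the in-band count matches the request.  Components sit on a
    grid with enough pitch that none touch.
    """
    gap = base_spec.gap_thickness
    met, epi = base_spec.plate_thickness
    for v in volumes:
        if v < gap:
            raise PhantomError(
                f"requested volume {v} cannot span a gap of {gap} voxels "
                f"(minimum spanning component is a {gap}-voxel column)"
            )
    # worst-case in-band blob: (max_v / gap) voxels per slice -> disk radius
    max_v = max(volumes)
    r_need = math.ceil(math.sqrt(max_v / gap / math.pi)) + 2
    pitch = 2 * r_need + 3
    cols = int(math.ceil(math.sqrt(len(volumes))))
    rows = int(math.ceil(len(volumes) / cols))
    margin = r_need + 3
    nx = margin * 2 + cols * pitch
    ny = margin * 2 + rows * pitch
    nz = met + gap + epi
    z_lo, z_hi = met, met + gap - 1

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[:, :, :z_lo] = METAPHYSIS
    labels[:, :, z_lo:z_hi + 1] = GROWTH_PLATE
    labels[:, :, z_hi + 1:] = EPIPHYSIS

    centers = []
    achieved = []
    for k, v in enumerate(volumes):
        cx = margin + (k % cols) * pitch
        cy = margin + (k // cols) * pitch
        # candidate in-band voxels sorted by (xy distance to column, z, y, x)
        extra = v - gap
        r_k = math.ceil(math.sqrt(v / gap / math.pi)) + 2
        xs = np.arange(cx - r_k, cx + r_k + 1)
        ys = np.arange(cy - r_k, cy + r_k + 1)
        X, Y, Z = np.meshgrid(xs, ys, np.arange(z_lo, z_hi + 1), indexing="ij")
        cand = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        d2 = (cand[:, 0] - cx) ** 2 + (cand[:, 1] - cy) ** 2
        order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2], d2))
        cand = cand[order]
        core = d2[order] == 0  # the column itself comes first
        chosen = np.concatenate([cand[core], cand[~core][:extra]])
        assert len(chosen) == v
        labels[tuple(chosen.T)] = BRIDGE
        centers.append(np.array([cx, cy, (z_lo + z_hi) / 2.0]))
        achieved.append(v)

    gl = base_spec.gray_levels
    means = np.array([gl.background_mean, gl.bone_mean, gl.bone_mean,
                      gl.cartilage_mean, gl.bone_mean])
    gray = means[labels].astype(np.float32)

    epi_mask = labels == EPIPHYSIS
    footprint = epi_mask.any(axis=2)
    truth = GroundTruth(
        labels=labels,
        gp_band=(z_lo, z_hi),
        bridge_volumes=achieved,
        bridge_centers_vox=centers,
        bridge_centers_um=[c * base_spec.voxel_size for c in centers],
        surface_height_vox=np.full(footprint.shape, nz - 1),
        surface_footprint=footprint,
        voxel_size=base_spec.voxel_size,
    )
    return Volume3D(gray, base_spec.voxel_size), truth
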