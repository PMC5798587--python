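from collections import deque

import numpy as np
import pytest

from physis import (
    BinaryMask,
    BridgeCylinder,
    GrayLevels,
    LabeledVolume,
    PhantomSpec,
    Undulation,
    generate_phantom,
)
from physis.segmentation import BRIDGE, EPIPHYSIS, METAPHYSIS


@pytest.fixture
def noiseless_phantom():
    """Two plates + 8-voxel gap crossed by two well-separated bridges."""
    spec = PhantomSpec(
        shape=(64, 64, 32),
        plate_thickness=(8, 8),
        gap_thickness=8,
        bridges=(BridgeCylinder((20.0, 20.0), 3.0), BridgeCylinder((44.0, 44.0), 2.5, 15.0)),
        undulation=Undulation(amplitude_vox=3.0, period_vox=32.0),
        gray_levels=GrayLevels(noise_sd=0.0),
        seed=11,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture
def labeled_from_truth():
    """Build (LabeledVolume, BinaryMask) straight from phantom ground truth."""

    def make(truth, voxel_size):
        bone = BinaryMask(
            np.isin(truth.labels, (EPIPHYSIS, METAPHYSIS, BRIDGE)), voxel_size)
        labeled = LabeledVolume(truth.labels, truth.gp_band, voxel_size)
        return labeled, bone

    return make


def bfs_flood(inside: np.ndarray, seeds, connectivity: int) -> np.ndarray:
    """Brute-force flood fill oracle, independent of scipy labeling."""
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)]
    out = np.zeros_like(inside, dtype=bool)
    q = deque()
    for s in seeds:
        s = tuple(int(v) for v in s)
        if inside[s] and not out[s]:
            out[s] = True
            q.append(s)
    shape = inside.shape
    while q:
        x, y, z = q.popleft()
        for dx, dy, dz in offs:
            n = (x + dx, y + dy, z + dz)
            if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]
                    and inside[n] and not out[n]):
                out[n] = True
                q.append(n)
    return out


def bfs_components(inside: np.ndarray, connectivity: int):
    """All connected components of a boolean volume via the BFS oracle."""
    remaining = inside.copy()
    comps = []
    while remaining.any():
        seed = tuple(np.argwhere(remaining)[0])
        comp = bfs_flood(remaining, [seed], connectivity)
        comps.append(comp)
        remaining &= ~comp
    return comps
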