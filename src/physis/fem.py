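"""Image-based linear-elastic finite elements on labeled microCT volumes.

Labeled voxels are binned (majority vote), decomposed into conforming
linear tetrahedra (5 per voxel, mirror-alternating with voxel parity so
shared faces match), and solved as a static isotropic linear-elasticity
problem with constant-strain TET4 elements.  Units are mm-MPa-N: voxel
sizes in μm are converted to mm at meshing so Young's moduli in MPa and
loads of order 1 N need no scaling.

Default materials (isotropic linear elastic): bone E = 17,000 MPa,
ν = 0.3; growth-plate cartilage E = 6 MPa, ν = 0.49.  The default loading
emulates static compression of the tibia: bottom nodes fixed vertically,
three pin constraints removing the remaining rigid-body modes, and a total
force of ~1 N (about three times mouse body weight) applied downward,
split between the medial and lateral halves of the top surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .segmentation import BACKGROUND, BRIDGE, EPIPHYSIS, GROWTH_PLATE, METAPHYSIS, LabeledVolume


class FEMError(ValueError):
    pass


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic material: Young's modulus (MPa), Poisson ratio."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise FEMError(f"Young's modulus must be positive, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise FEMError(f"Poisson ratio must be in (-1, 0.5), got {self.nu}")

    @property
    def D(self) -> np.ndarray:
        """6x6 constitutive matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] = lam + 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D


BONE = MaterialModel(E=17_000.0, nu=0.3)
GROWTH_PLATE_CARTILAGE = MaterialModel(E=6.0, nu=0.49)

#: default mapping from tissue labels to materials (bridges are bone)
DEFAULT_MATERIALS = {
    EPIPHYSIS: BONE,
    METAPHYSIS: BONE,
    BRIDGE: BONE,
    GROWTH_PLATE: GROWTH_PLATE_CARTILAGE,
}


@dataclass
class TetMesh:
    """Linear tetrahedral mesh: node coordinates (mm), element connectivity,
    per-element material id (the originating tissue label)."""

    nodes: np.ndarray      # (n_nodes, 3) mm
    elements: np.ndarray   # (n_el, 4) node indices, positively oriented
    material_id: np.ndarray  # (n_el,)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        n = self.nodes
        e = self.elements
        a = n[e[:, 1]] - n[e[:, 0]]
        b = n[e[:, 2]] - n[e[:, 0]]
        c = n[e[:, 3]] - n[e[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


@dataclass
class LoadCase:
    """Boundary conditions: vertical fixity at the bottom, three pins
    removing in-plane rigid modes, nodal forces, and (optionally) fully
    prescribed nodal displacements, e.g. for patch tests."""

    fixed_bottom: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pin_xyz: int | None = None        # node fixed in x, y, z
    pin_x: int | None = None          # node fixed in x
    pin_y: int | None = None          # node fixed in y
    forces: dict = field(default_factory=dict)       # node id -> 3-vector N
    prescribed: dict = field(default_factory=dict)   # node id -> 3-vector mm

    def constrained(self) -> tuple:
        """(dof indices, prescribed values) for all displacement constraints."""
        dofs: dict = {}
        for n in np.asarray(self.fixed_bottom, dtype=int):
            dofs[3 * int(n) + 2] = 0.0
        if self.pin_xyz is not None:
            for k in range(3):
                dofs[3 * self.pin_xyz + k] = 0.0
        if self.pin_x is not None:
            dofs[3 * self.pin_x] = 0.0
        if self.pin_y is not None:
            dofs[3 * self.pin_y + 1] = 0.0
        for n, vec in self.prescribed.items():
            for k in range(3):
                dofs[3 * int(n) + k] = float(np.asarray(vec)[k])
        idx = np.array(sorted(dofs), dtype=int)
        vals = np.array([dofs[i] for i in idx])
        return idx, vals

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        for node, vec in self.forces.items():
            f[3 * node:3 * node + 3] += np.asarray(vec, dtype=float)
        return f


@dataclass
class FEResult:
    displacements: np.ndarray   # (n_nodes, 3) mm
    stress: np.ndarray          # (n_el, 6) Voigt (xx, yy, zz, xy, yz, zx) MPa
    von_mises_stress: np.ndarray  # (n_el,) MPa
    reactions: np.ndarray       # (n_dof,) N, nonzero only at constrained dofs
    residual: float             # |K u - f| relative to |f| on free dofs


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

# 5-tet decompositions of the unit cube; corners indexed bit-wise
# v = (x | y<<1 | z<<2).  The two mirror variants share face diagonals with
# their neighbors when alternated by voxel parity (x+y+z even/odd).
_TETS_EVEN = np.array([
    [0, 1, 3, 5],
    [0, 3, 2, 6],
    [0, 5, 4, 6],
    [3, 5, 6, 7],
    [0, 3, 5, 6],
])
_TETS_ODD = np.array([
    [1, 0, 2, 4],
    [1, 2, 3, 7],
    [1, 4, 5, 7],
    [2, 4, 6, 7],
    [1, 2, 4, 7],
])
_CORNER_OFFSETS = np.array([[(v >> 0) & 1, (v >> 1) & 1, (v >> 2) & 1] for v in range(8)])


def bin_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Majority-vote label downsampling by an integer factor (ties: smallest
    label wins; background competes like any label)."""
    if factor < 1:
        raise FEMError(f"bin_factor must be >= 1, got {factor}")
    if factor == 1:
        return labels
    nx, ny, nz = labels.shape
    pad = [(0, (-s) % factor) for s in labels.shape]
    lab = np.pad(labels, pad, constant_values=BACKGROUND)
    sx, sy, sz = (s // factor for s in lab.shape)
    blocks = lab.reshape(sx, factor, sy, factor, sz, factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(sx, sy, sz, -1)
    n_lab = int(labels.max()) + 1
    counts = np.stack([(blocks == l).sum(axis=-1) for l in range(n_lab)], axis=-1)
    return counts.argmax(axis=-1).astype(labels.dtype)


def mesh_from_labels(labeled: LabeledVolume, bin_factor: int = 1) -> TetMesh:
    """Conforming TET4 mesh of all non-background voxels.

    Each retained binned voxel becomes 5 tetrahedra (parity-alternating
    decomposition), material from the voxel label; the summed tetra volume
    equals the retained voxel volume exactly.  Node coordinates are mm.
    """
    lab = bin_labels(labeled.labels, bin_factor)
    vox = np.argwhere(lab != BACKGROUND)
    if len(vox) == 0:
        raise FEMError("no non-background voxels to mesh")
    h = labeled.voxel_size * bin_factor * 1e-3  # μm -> mm

    # global corner-node lattice keys
    corner = vox[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (n_vox, 8, 3)
    shape1 = lab.shape[0] + 1, lab.shape[1] + 1, lab.shape[2] + 1
    keys = np.ravel_multi_index(corner.reshape(-1, 3).T, shape1)
    uniq, inv = np.unique(keys, return_inverse=True)
    corner_ids = inv.reshape(len(vox), 8)
    nodes = np.stack(np.unravel_index(uniq, shape1), axis=1).astype(float) * h

    parity = vox.sum(axis=1) % 2
    elements = np.empty((len(vox), 5, 4), dtype=int)
    even = parity == 0
    elements[even] = corner_ids[even][:, _TETS_EVEN]
    elements[~even] = corner_ids[~even][:, _TETS_ODD]
    elements = elements.reshape(-1, 4)
    material = np.repeat(lab[tuple(vox.T)], 5)

    mesh = TetMesh(nodes, elements, material)
    # enforce positive orientation
    vols = mesh.element_volumes()
    flip = vols < 0
    if flip.any():
        mesh.elements[flip, 2], mesh.elements[flip, 3] = (
            mesh.elements[flip, 3].copy(), mesh.elements[flip, 2].copy())
    if (mesh.element_volumes() <= 0).any():
        raise FEMError("degenerate tetrahedra produced")
    return mesh


# ---------------------------------------------------------------------------
# Assembly and solution
# ---------------------------------------------------------------------------

def _element_B_V(nodes: np.ndarray, el: np.ndarray):
    """Strain-displacement matrices (6x12) and volumes for all elements."""
    x = nodes[el]  # (n_el, 4, 3)
    ones = np.ones((len(el), 4, 1))
    M = np.concatenate([ones, x], axis=2)  # (n_el, 4, 4)
    detM = np.linalg.det(M)
    V = detM / 6.0
    Minv = np.linalg.inv(M)
    # shape-function gradients: dN_a/dx_i = Minv[i+1, a]
    grads = Minv[:, 1:, :].transpose(0, 2, 1)  # (n_el, 4, 3)
    B = np.zeros((len(el), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, V


def _check_rigid_modes(mesh: TetMesh, constrained: np.ndarray) -> None:
    """Verify the constraints restrain all 6 rigid-body modes; name the
    unconstrained mode otherwise."""
    coords = mesh.nodes
    n = len(coords)
    modes = np.zeros((6, 3 * n))
    names = ["translation x", "translation y", "translation z",
             "rotation about x", "rotation about y", "rotation about z"]
    for i in range(3):
        modes[i, i::3] = 1.0
    c = coords - coords.mean(axis=0)
    modes[3, 1::3], modes[3, 2::3] = -c[:, 2], c[:, 1]
    modes[4, 0::3], modes[4, 2::3] = c[:, 2], -c[:, 0]
    modes[5, 0::3], modes[5, 1::3] = -c[:, 1], c[:, 0]
    if len(constrained) == 0:
        raise FEMError(f"singular system: unconstrained rigid-body mode: {names[0]}")
    sub = modes[:, constrained]
    # a rigid mode is unrestrained iff some combination of modes vanishes on
    # the constrained dofs, i.e. sub is rank-deficient
    u, s, _ = np.linalg.svd(sub, full_matrices=True)
    scale = np.abs(sub).max() + 1e-30
    s_full = np.zeros(6)
    s_full[:len(s)] = s
    rank = int((s_full / scale > 1e-10).sum())
    if rank < 6:
        null = u[:, rank]
        worst = int(np.argmax(np.abs(null)))
        raise FEMError(f"singular system: unconstrained rigid-body mode: {names[worst]}")


def assemble_stiffness(mesh: TetMesh, materials: dict) -> sparse.csr_matrix:
    """Global stiffness K (3 dof/node) from constant-strain tetrahedra."""
    for mid in np.unique(mesh.material_id):
        if mid not in materials:
            raise FEMError(f"no material mapped for material_id {mid}")
    B, V = _element_B_V(mesh.nodes, mesh.elements)
    n_el = mesh.n_elements
    Ke = np.empty((n_el, 12, 12))
    for mid in np.unique(mesh.material_id):
        sel = mesh.material_id == mid
        D = materials[mid].D
        BD = np.einsum("eji,jk->eik", B[sel], D)       # B^T D
        Ke[sel] = np.einsum("eik,ekl->eil", BD, B[sel]) * V[sel, None, None]
    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(n_el, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes))
    return K.tocsr()


def assemble_and_solve(mesh: TetMesh, materials: dict, load: LoadCase) -> FEResult:
    """Solve K u = f with zero-displacement constraints; return displacement,
    per-element stress, von Mises, reactions, and the relative residual."""
    constrained, values = load.constrained()
    _check_rigid_modes(mesh, constrained)
    K = assemble_stiffness(mesh, materials)
    n_dof = 3 * mesh.n_nodes
    f = load.force_vector(mesh.n_nodes)

    free = np.setdiff1d(np.arange(n_dof), constrained, assume_unique=False)
    u = np.zeros(n_dof)
    u[constrained] = values
    rhs = f[free] - K[free][:, constrained] @ values
    if np.any(rhs):
        u[free] = spsolve(K[free][:, free].tocsc(), rhs)
    r = K @ u - f
    scale = max(np.linalg.norm(f), np.linalg.norm(K @ u))
    residual = float(np.linalg.norm(r[free]) / scale) if scale > 0 else 0.0

    reactions = np.zeros(n_dof)
    reactions[constrained] = r[constrained]

    B, V = _element_B_V(mesh.nodes, mesh.elements)
    ue = u.reshape(-1, 3)[mesh.elements].reshape(mesh.n_elements, 12)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.empty_like(strain)
    for mid in np.unique(mesh.material_id):
        sel = mesh.material_id == mid
        stress[sel] = strain[sel] @ materials[mid].D.T
    vm = von_mises_voigt(stress)
    return FEResult(u.reshape(-1, 3), stress, vm, reactions, residual)


def von_mises(stress_tensor: np.ndarray) -> float:
    """Von Mises equivalent stress of a symmetric 3x3 tensor:
    sqrt(0.5[(s11-s22)^2+(s22-s33)^2+(s33-s11)^2] + 3(s12^2+s23^2+s31^2))."""
    s = np.asarray(stress_tensor, dtype=float)
    if s.shape != (3, 3) or not np.allclose(s, s.T, atol=1e-9 * max(1.0, np.abs(s).max())):
        raise FEMError("stress tensor must be symmetric 3x3")
    return float(np.sqrt(
        0.5 * ((s[0, 0] - s[1, 1]) ** 2 + (s[1, 1] - s[2, 2]) ** 2 + (s[2, 2] - s[0, 0]) ** 2)
        + 3.0 * (s[0, 1] ** 2 + s[1, 2] ** 2 + s[2, 0] ** 2)
    ))


def von_mises_voigt(stress: np.ndarray) -> np.ndarray:
    """Vectorized von Mises for (n, 6) Voigt stresses (xx, yy, zz, xy, yz, zx)."""
    s = np.asarray(stress, dtype=float)
    return np.sqrt(
        0.5 * ((s[:, 0] - s[:, 1]) ** 2 + (s[:, 1] - s[:, 2]) ** 2 + (s[:, 2] - s[:, 0]) ** 2)
        + 3.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
    )


# ---------------------------------------------------------------------------
# Load-case construction
# ---------------------------------------------------------------------------

def _extremal_pins(nodes: np.ndarray, node_set: np.ndarray):
    """Deterministic pin choice on a node set.

    The fully fixed pin A is the lexicographic min-(x, y) node.  The x-pin
    must differ from A in y (an x-restraint at equal y cannot block
    rotation about z), so it goes on the max-y node; symmetrically the
    y-pin goes on the max-x node.
    """
    pts = nodes[node_set]
    pin_xyz = node_set[np.lexsort((pts[:, 1], pts[:, 0]))[0]]
    pin_x = node_set[np.lexsort((pts[:, 0], -pts[:, 1]))[0]]   # max y
    pin_y = node_set[np.lexsort((pts[:, 1], -pts[:, 0]))[0]]   # max x
    return int(pin_xyz), int(pin_x), int(pin_y)


def surface_node_sets(mesh: TetMesh, tol: float = 1e-9):
    """Bottom (min z) and top (max z) node sets."""
    z = mesh.nodes[:, 2]
    bottom = np.nonzero(z <= z.min() + tol)[0]
    top = np.nonzero(z >= z.max() - tol)[0]
    return bottom, top


def uniform_node_loads(node_set: np.ndarray, total_force: float,
                       direction=(0.0, 0.0, -1.0)) -> dict:
    """Split a total force equally over the nodes of a set."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    per = total_force / len(node_set)
    return {int(n): per * d for n in node_set}


def tributary_node_loads(mesh: TetMesh, node_set: np.ndarray, total_force: float,
                         direction=(0.0, 0.0, -1.0)) -> dict:
    """Area-consistent nodal forces for uniform traction on the boundary
    faces whose three corners all lie in ``node_set`` (1/3 of each triangle
    area per corner).  Reproduces uniform-stress states exactly."""
    in_set = np.zeros(mesh.n_nodes, dtype=bool)
    in_set[node_set] = True
    faces = {}
    fi = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for el in mesh.elements:
        for i, j, k in fi:
            key = tuple(sorted((el[i], el[j], el[k])))
            faces[key] = faces.get(key, 0) + 1
    weight = np.zeros(mesh.n_nodes)
    for key, cnt in faces.items():
        if cnt != 1:
            continue  # interior face
        a, b, c = key
        if not (in_set[a] and in_set[b] and in_set[c]):
            continue
        area = 0.5 * np.linalg.norm(np.cross(mesh.nodes[b] - mesh.nodes[a],
                                             mesh.nodes[c] - mesh.nodes[a]))
        for n in key:
            weight[n] += area / 3.0
    total = weight.sum()
    if total <= 0:
        raise FEMError("node set spans no boundary faces; cannot build tributary loads")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return {int(n): total_force * (weight[n] / total) * d
            for n in np.nonzero(weight)[0]}


def default_tibia_load_case(mesh: TetMesh, total_force: float = 1.0,
                            consistent: bool = False) -> LoadCase:
    """Static compression: bottom vertical fixity + three pins; ~1 N total
    (about three times mouse body weight) applied downward, split equally
    between the medial and lateral halves of the top surface."""
    bottom, top = surface_node_sets(mesh)
    pin_xyz, pin_x, pin_y = _extremal_pins(mesh.nodes, bottom)
    x_mid = np.median(mesh.nodes[top, 0])
    medial = top[mesh.nodes[top, 0] <= x_mid]
    lateral = top[mesh.nodes[top, 0] > x_mid]
    if len(lateral) == 0:  # degenerate split (tiny meshes): load all top nodes
        medial, lateral = top, np.array([], dtype=int)
    forces: dict = {}
    halves = [s for s in (medial, lateral) if len(s)]
    for s in halves:
        if consistent:
            part = tributary_node_loads(mesh, s, total_force / len(halves))
        else:
            part = uniform_node_loads(s, total_force / len(halves))
        for n, v in part.items():
            forces[n] = forces.get(n, np.zeros(3)) + v
    return LoadCase(fixed_bottom=bottom, pin_xyz=pin_xyz, pin_x=pin_x, pin_y=pin_y,
                    forces=forces)


# ---------------------------------------------------------------------------
# Mesh sensitivity
# ---------------------------------------------------------------------------

def mesh_sensitivity(results: list, rel_tol: float = 0.05):
    """Pick the coarsest mesh whose metric is within ``rel_tol`` (default 5%)
    of the asymptotic value, estimated as the finest-mesh metric.

    ``results`` is a list of (element_count, metric) with strictly
    increasing counts, at least three entries.  Returns
    ``(chosen_element_count, table)`` where the table reports the relative
    deviation of every mesh from the asymptote.
    """
    if len(results) < 3:
        raise FEMError("mesh sensitivity needs at least 3 (element_count, metric) entries")
    counts = [int(c) for c, _ in results]
    metrics = [float(m) for _, m in results]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise FEMError("element counts must be strictly increasing")
    asymptote = metrics[-1]
    denom = abs(asymptote) if asymptote != 0 else 1.0
    dev = [abs(m - asymptote) / denom for m in metrics]
    table = pd.DataFrame({"element_count": counts, "metric": metrics,
                          "rel_deviation": dev})
    for c, d in zip(counts, dev):
        if d <= rel_tol:
            return c, table
    raise FEMError(f"no mesh within {rel_tol:.0%} of the asymptotic value:\n{table}")


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: TetMesh, result: FEResult | None = None) -> Path:
    """Write the mesh (and optionally displacements + von Mises) as a legacy
    ASCII VTK unstructured grid readable by ParaView."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nphysis FE mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        f.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for e in mesh.elements:
            f.write(f"4 {e[0]} {e[1]} {e[2]} {e[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        f.write("\n".join(["10"] * mesh.n_elements) + "\n")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        f.write("SCALARS material_id int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(m)) for m in mesh.material_id) + "\n")
        if result is not None:
            f.write("SCALARS von_mises float 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.6g}" for v in result.von_mises_stress) + "\n")
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            f.write("VECTORS displacement float\n")
            for u in result.displacements:
                f.write(f"{u[0]:.6g} {u[1]:.6g} {u[2]:.6g}\n")
    return path
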