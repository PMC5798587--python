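import numpy as np
import pytest

from physis import (
    BONE,
    GROWTH_PLATE_CARTILAGE,
    LabeledVolume,
    LoadCase,
    MaterialModel,
    assemble_and_solve,
    default_tibia_load_case,
    mesh_from_labels,
    mesh_sensitivity,
    von_mises,
)
from physis.fem import (
    FEMError,
    _extremal_pins,
    bin_labels,
    surface_node_sets,
    tributary_node_loads,
    write_vtk,
)
from physis.segmentation import BACKGROUND, EPIPHYSIS, GROWTH_PLATE


def block_labels(shape, label=EPIPHYSIS, voxel_um=1000.0):
    return LabeledVolume(np.full(shape, label, np.uint8), (0, 0), voxel_um)


def column_load(mesh, total_force):
    bottom, top = surface_node_sets(mesh)
    pxyz, px, py = _extremal_pins(mesh.nodes, bottom)
    return LoadCase(fixed_bottom=bottom, pin_xyz=pxyz, pin_x=px, pin_y=py,
                    forces=tributary_node_loads(mesh, top, total_force))


class TestMeshing:
    def test_single_voxel_is_five_tets_of_total_volume_h3(self):
        mesh = mesh_from_labels(block_labels((1, 1, 1)))  # 1 mm voxel
        assert mesh.n_elements == 5
        assert np.isclose(mesh.element_volumes().sum(), 1.0)
        assert (mesh.element_volumes() > 0).all()

    def test_2x2x2_block_is_conforming(self):
        mesh = mesh_from_labels(block_labels((2, 2, 2)))
        assert mesh.n_elements == 40
        from collections import Counter
        faces = Counter()
        for e in mesh.elements:
            for i, j, k in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
                faces[tuple(sorted((e[i], e[j], e[k])))] += 1
        assert set(faces.values()) <= {1, 2}  # boundary faces once, interior twice
        assert np.isclose(mesh.element_volumes().sum(), 8.0)

    def test_mesh_volume_equals_retained_voxel_volume(self):
        labels = np.full((4, 4, 6), EPIPHYSIS, np.uint8)
        labels[0, 0, :] = BACKGROUND
        lab = LabeledVolume(labels, (0, 0), 500.0)  # 0.5 mm voxels
        mesh = mesh_from_labels(lab)
        assert np.isclose(mesh.element_volumes().sum(), (4 * 4 * 6 - 6) * 0.5**3)

    def test_empty_label_volume_is_an_error(self):
        with pytest.raises(FEMError):
            mesh_from_labels(block_labels((2, 2, 2), label=BACKGROUND))

    def test_bad_bin_factor_is_an_error(self):
        with pytest.raises(FEMError):
            mesh_from_labels(block_labels((2, 2, 2)), bin_factor=0)

    def test_majority_vote_binning(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        labels[:2, :2, :2] = EPIPHYSIS          # 8 of 8 in block (0,0,0)
        labels[2:, 2:, 2:] = GROWTH_PLATE
        labels[2, 2, 2] = EPIPHYSIS             # 7 GP vs 1 EPI in block (1,1,1)
        out = bin_labels(labels, 2)
        assert out.shape == (2, 2, 2)
        assert out[0, 0, 0] == EPIPHYSIS
        assert out[1, 1, 1] == GROWTH_PLATE
        assert out[1, 0, 0] == BACKGROUND

    def test_material_ids_follow_labels(self):
        labels = np.full((2, 2, 4), EPIPHYSIS, np.uint8)
        labels[:, :, :2] = GROWTH_PLATE
        mesh = mesh_from_labels(LabeledVolume(labels, (0, 1), 1000.0))
        assert set(np.unique(mesh.material_id)) == {EPIPHYSIS, GROWTH_PLATE}


class TestMaterials:
    def test_table_defaults(self):
        assert BONE.E == 17_000.0 and BONE.nu == 0.3
        assert GROWTH_PLATE_CARTILAGE.E == 6.0 and GROWTH_PLATE_CARTILAGE.nu == 0.49

    @pytest.mark.parametrize("E,nu", [(-1.0, 0.3), (10.0, 0.5), (10.0, -1.0)])
    def test_invalid_materials_rejected(self, E, nu):
        with pytest.raises(FEMError):
            MaterialModel(E=E, nu=nu)


class TestSolve:
    def test_zero_load_zero_displacement(self):
        mesh = mesh_from_labels(block_labels((2, 2, 4)))
        res = assemble_and_solve(mesh, {EPIPHYSIS: BONE}, column_load(mesh, 0.0))
        assert np.abs(res.displacements).max() == 0.0

    @pytest.mark.parametrize("mat", [BONE, GROWTH_PLATE_CARTILAGE],
                             ids=["bone", "growth-plate"])
    def test_patch_test_reproduces_linear_field(self, mat):
        """TET4 must reproduce a uniform strain state exactly."""
        mesh = mesh_from_labels(block_labels((3, 3, 3)))
        A = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4], [0.0, 1e-4, 3e-4]])
        nodes = mesh.nodes
        bmin, bmax = nodes.min(0), nodes.max(0)
        boundary = (np.isclose(nodes, bmin) | np.isclose(nodes, bmax)).any(axis=1)
        load = LoadCase(prescribed={int(n): A @ nodes[n]
                                    for n in np.nonzero(boundary)[0]})
        res = assemble_and_solve(mesh, {EPIPHYSIS: mat}, load)
        u_exact = nodes @ A.T
        assert np.abs(res.displacements - u_exact).max() <= 1e-8 * np.abs(u_exact).max()
        assert res.stress.std(axis=0).max() <= 1e-8 * np.abs(res.stress).max()

    def test_column_matches_bar_solution(self):
        mesh = mesh_from_labels(block_labels((4, 4, 16)))  # 4x4 mm², 16 mm tall
        E, F, L, A = 100.0, 10.0, 16.0, 16.0
        load = column_load(mesh, F)
        res = assemble_and_solve(mesh, {EPIPHYSIS: MaterialModel(E=E, nu=0.0)}, load)
        _, top = surface_node_sets(mesh)
        tip = res.displacements[top, 2].mean()
        assert abs(tip - (-F * L / (E * A))) <= 0.005 * F * L / (E * A)

    def test_two_layer_column_matches_series_springs(self):
        labels = np.full((4, 4, 16), EPIPHYSIS, np.uint8)
        labels[:, :, :8] = GROWTH_PLATE
        mesh = mesh_from_labels(LabeledVolume(labels, (0, 7), 1000.0))
        mats = {EPIPHYSIS: MaterialModel(17_000.0, 0.0), GROWTH_PLATE: MaterialModel(6.0, 0.0)}
        F, A = 10.0, 16.0
        res = assemble_and_solve(mesh, mats, column_load(mesh, F))
        _, top = surface_node_sets(mesh)
        tip = res.displacements[top, 2].mean()
        exact = -F * (8.0 / 17_000.0 + 8.0 / 6.0) / A
        assert abs(tip - exact) <= 0.01 * abs(exact)

    def test_equilibrium_reactions_balance_loads(self):
        mesh = mesh_from_labels(block_labels((3, 3, 8)))
        load = column_load(mesh, 5.0)
        res = assemble_and_solve(mesh, {EPIPHYSIS: BONE}, load)
        f = load.force_vector(mesh.n_nodes).reshape(-1, 3).sum(axis=0)
        r = res.reactions.reshape(-1, 3).sum(axis=0)
        assert np.abs(f + r).max() <= 1e-8 * np.linalg.norm(load.force_vector(mesh.n_nodes))
        assert res.residual <= 1e-10

    def test_missing_restraint_names_the_rigid_mode(self):
        mesh = mesh_from_labels(block_labels((2, 2, 4)))
        bottom, top = surface_node_sets(mesh)
        load = LoadCase(fixed_bottom=bottom)  # no pins: in-plane modes free
        with pytest.raises(FEMError, match="rigid-body mode"):
            assemble_and_solve(mesh, {EPIPHYSIS: BONE}, load)

    def test_unmapped_material_is_an_error(self):
        mesh = mesh_from_labels(block_labels((2, 2, 2)))
        with pytest.raises(FEMError, match="material"):
            assemble_and_solve(mesh, {GROWTH_PLATE: BONE}, column_load(mesh, 1.0))


class TestVonMises:
    def test_uniaxial(self):
        assert np.isclose(von_mises(np.diag([10.0, 0, 0])), 10.0)

    def test_hydrostatic_is_zero(self):
        assert np.isclose(von_mises(np.eye(3) * 7.0), 0.0)

    def test_pure_shear(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 5.0
        assert np.isclose(von_mises(s), 5.0 * np.sqrt(3.0))

    def test_asymmetric_tensor_rejected(self):
        s = np.zeros((3, 3))
        s[0, 1] = 1.0
        with pytest.raises(FEMError):
            von_mises(s)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=(3, 3))
        s = (s + s.T) / 2
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        assert np.isclose(von_mises(q @ s @ q.T), von_mises(s), atol=1e-10)


class TestMeshSensitivity:
    def test_picks_first_mesh_within_five_percent(self):
        series = [(1000, 10.0), (2000, 6.0), (4000, 5.2), (8000, 5.05), (16000, 5.0)]
        chosen, table = mesh_sensitivity(series)
        assert chosen == 4000  # |5.2-5.0|/5.0 = 4% <= 5%
        assert len(table) == 5

    def test_constant_series_picks_coarsest(self):
        chosen, _ = mesh_sensitivity([(100, 3.0), (200, 3.0), (400, 3.0)])
        assert chosen == 100

    def test_needs_three_entries(self):
        with pytest.raises(FEMError):
            mesh_sensitivity([(100, 2.0), (200, 1.0)])

    def test_counts_must_increase(self):
        with pytest.raises(FEMError):
            mesh_sensitivity([(100, 2.0), (100, 1.5), (200, 1.0)])


class TestExport:
    def test_vtk_file_is_readable_text(self, tmp_path):
        mesh = mesh_from_labels(block_labels((2, 2, 2)))
        res = assemble_and_solve(mesh, {EPIPHYSIS: BONE}, column_load(mesh, 1.0))
        path = write_vtk(tmp_path / "out.vtk", mesh, res)
        text = path.read_text()
        assert "UNSTRUCTURED_GRID" in text
        assert f"POINTS {mesh.n_nodes} float" in text
        assert "von_mises" in text


class TestDefaultLoadCase:
    def test_total_force_one_newton_split_over_two_regions(self):
        mesh = mesh_from_labels(block_labels((6, 6, 8)))
        load = default_tibia_load_case(mesh)
        f = load.force_vector(mesh.n_nodes).reshape(-1, 3)
        assert np.isclose(f[:, 2].sum(), -1.0)
        assert np.allclose(f[:, :2], 0.0)
        # both medial (low x) and lateral (high x) halves carry half the load
        x = mesh.nodes[:, 0]
        xm = np.median(x[f[:, 2] < 0])
        assert np.isclose(f[x <= xm, 2].sum(), -0.5, atol=1e-9)
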