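import numpy as np
import pytest

from physis import (
    BinaryMask,
    Bridge,
    BridgeFilterParams,
    BridgeSet,
    LabeledVolume,
    PhantomSpec,
    bridge_centers,
    filter_by_volume,
    find_candidate_bridges,
    sweep_bridge_volumes,
)
from physis.segmentation import BRIDGE, EPIPHYSIS, GROWTH_PLATE, METAPHYSIS, SegmentationError

from conftest import bfs_components


def band_phantom(band_bone: np.ndarray, gap=(10, 20)):
    """Labels/mask with solid plates and the given in-band bone pattern."""
    nx, ny, _ = band_bone.shape
    nz = band_bone.shape[2] + gap[0] + (gap[0])  # plates same thickness as z_lo
    z_lo, z_hi = gap[0], gap[0] + band_bone.shape[2] - 1
    shape = (nx, ny, z_hi + 1 + gap[0])
    labels = np.zeros(shape, dtype=np.uint8)
    labels[:, :, :z_lo] = METAPHYSIS
    labels[:, :, z_hi + 1:] = EPIPHYSIS
    labels[:, :, z_lo:z_hi + 1][band_bone] = BRIDGE
    labels[:, :, z_lo:z_hi + 1][~band_bone] = GROWTH_PLATE
    bone = np.isin(labels, (EPIPHYSIS, METAPHYSIS, BRIDGE))
    return LabeledVolume(labels, (z_lo, z_hi), 5.0), BinaryMask(bone, 5.0)


def cylinder_band(centers, radius=2.5, shape=(48, 48, 8)):
    band = np.zeros(shape, dtype=bool)
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for cx, cy in centers:
        band |= ((X - cx) ** 2 + (Y - cy) ** 2 <= radius**2)[:, :, None]
    return band


class TestFindCandidateBridges:
    def test_three_separated_cylinders(self):
        labeled, bone = band_phantom(cylinder_band([(10, 10), (24, 24), (38, 12)]))
        bs = find_candidate_bridges(labeled, bone)
        assert len(bs) == 3
        assert all(b.spans for b in bs)

    def test_spur_touching_one_side_excluded(self):
        band = np.zeros((20, 20, 8), dtype=bool)
        band[5, 5, :] = True       # full crossing column
        band[12, 12, :4] = True    # spur attached to the metaphysis only
        labeled, bone = band_phantom(band)
        bs = find_candidate_bridges(labeled, bone)
        assert len(bs) == 1
        assert bs.bridges[0].voxel_count == 8

    def test_merging_cylinders_count_as_one(self):
        # two columns joined by an in-band horizontal bar -> one Y-shaped component
        band = np.zeros((20, 20, 8), dtype=bool)
        band[5, 5, :] = True
        band[9, 5, :] = True
        band[5:10, 5, 4] = True
        labeled, bone = band_phantom(band)
        bs = find_candidate_bridges(labeled, bone)
        assert len(bs) == 1

    def test_ids_ordered_by_bbox_corner(self):
        labeled, bone = band_phantom(cylinder_band([(30, 8), (8, 30), (8, 8)]))
        bs = find_candidate_bridges(labeled, bone)
        corners = [(b.bbox[2][0], b.bbox[1][0], b.bbox[0][0]) for b in bs.bridges]
        assert corners == sorted(corners)
        assert [b.id for b in bs.bridges] == [1, 2, 3]

    def test_seed_list_restricts_to_clicked_components(self):
        labeled, bone = band_phantom(cylinder_band([(10, 10), (30, 30)]))
        bs = find_candidate_bridges(labeled, bone, seeds=[(10, 10, 12)])
        assert len(bs) == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force_oracle(self, connectivity, seed):
        """Spanning components on random in-band patterns, voxel for voxel.

        With solid plates, a band component spans iff it reaches both the
        first and last band slice; the oracle labels components by BFS.
        """
        rng = np.random.default_rng(100 + seed)
        band = rng.random((16, 16, 6)) < 0.18
        labeled, bone = band_phantom(band)
        bs = find_candidate_bridges(labeled, bone, connectivity=connectivity)

        expected = []
        for comp in bfs_components(band, connectivity):
            zs = np.nonzero(comp)[2]
            if zs.min() == 0 and zs.max() == band.shape[2] - 1:
                expected.append(comp)
        assert len(bs) == len(expected)
        got = np.zeros(band.shape, dtype=bool)
        for b in bs.bridges:
            got[b.voxels[:, 0], b.voxels[:, 1], b.voxels[:, 2] - labeled.gp_band[0]] = True
        np.testing.assert_array_equal(got, np.logical_or.reduce(expected) if expected
                                      else np.zeros_like(band))

    def test_voxel_sum_bounded_by_band_mineral(self):
        rng = np.random.default_rng(42)
        band = rng.random((16, 16, 6)) < 0.25
        labeled, bone = band_phantom(band)
        bs = find_candidate_bridges(labeled, bone)
        assert sum(b.voxel_count for b in bs) <= band.sum()

    def test_empty_compartment_is_an_error(self):
        labels = np.zeros((8, 8, 12), dtype=np.uint8)
        labels[:, :, :4] = METAPHYSIS
        labels[:, :, 4:8] = GROWTH_PLATE
        labeled = LabeledVolume(labels, (4, 7), 5.0)
        with pytest.raises(SegmentationError):
            find_candidate_bridges(labeled, BinaryMask(labels == METAPHYSIS, 5.0))


class TestFilterByVolume:
    def test_boundary_semantics_125_retained_124_removed(self):
        vol, truth = sweep_bridge_volumes(PhantomSpec(gap_thickness=5), [124, 125])
        labeled = LabeledVolume(truth.labels, truth.gp_band, truth.voxel_size)
        bone = BinaryMask(np.isin(truth.labels, (EPIPHYSIS, METAPHYSIS, BRIDGE)),
                          truth.voxel_size)
        bs = filter_by_volume(find_candidate_bridges(labeled, bone))
        assert [b.voxel_count for b in bs.bridges] == [125]

    def test_empty_set_stays_empty(self):
        bs = BridgeSet([], 5.0)
        assert len(filter_by_volume(bs)) == 0

    def test_min_one_is_identity(self):
        labeled, bone = band_phantom(cylinder_band([(10, 10)]))
        bs = find_candidate_bridges(labeled, bone)
        out = filter_by_volume(bs, BridgeFilterParams(min_voxels=1))
        assert [b.id for b in out.bridges] == [b.id for b in bs.bridges]

    def test_idempotent_and_monotone(self):
        labeled, bone = band_phantom(cylinder_band([(10, 10), (30, 30)], radius=1.5))
        bs = find_candidate_bridges(labeled, bone)
        params = BridgeFilterParams(min_voxels=20)
        once = filter_by_volume(bs, params)
        twice = filter_by_volume(once, params)
        assert [b.id for b in once.bridges] == [b.id for b in twice.bridges]
        sizes = [len(filter_by_volume(bs, BridgeFilterParams(min_voxels=m)))
                 for m in (1, 10, 50, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_min_voxels_must_be_positive(self):
        with pytest.raises(ValueError):
            BridgeFilterParams(min_voxels=0)


def bridge_from_voxels(vox, voxel_size=1.0):
    vox = np.asarray(vox, dtype=int)
    b = Bridge(1, len(vox), float(len(vox)) * voxel_size**3, None, None,
               {"epiphysis": True, "metaphysis": True}, vox)
    return BridgeSet([b], voxel_size)


class TestBridgeCenters:
    def test_single_voxel_center_is_that_voxel(self):
        bs = bridge_centers(bridge_from_voxels([(3, 4, 5)], voxel_size=5.0))
        np.testing.assert_allclose(bs.bridges[0].center, (15.0, 20.0, 25.0))

    def test_straight_cylinder_center_near_midpoint(self):
        vox = [(x, y, z) for z in range(20) for x in range(4, 9) for y in range(4, 9)
               if (x - 6) ** 2 + (y - 6) ** 2 <= 4]
        bs = bridge_centers(bridge_from_voxels(vox))
        assert np.linalg.norm(bs.bridges[0].center - np.array([6, 6, 9.5])) <= 1.0

    def test_l_shape_skeleton_center_inside_but_centroid_outside(self):
        vox = [(x, 0, 0) for x in range(10)] + [(9, y, 0) for y in range(1, 10)]
        vox_set = set(vox)
        inside = lambda c: tuple(np.rint(c).astype(int)) in vox_set
        sk = bridge_centers(bridge_from_voxels(vox), "skeleton").bridges[0].center
        cen = bridge_centers(bridge_from_voxels(vox), "centroid").bridges[0].center
        assert inside(sk)
        assert not inside(cen)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            bridge_centers(bridge_from_voxels([(0, 0, 0)]), "magic")
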