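"""Map I/O, segmentation, alignment, averaging, FSC."""

import numpy as np
import pytest

from helixtrace import synthetic_data as sd
from helixtrace.map_ops import (
    DensityMap,
    RigidTransform,
    align_maps,
    average_maps,
    fsc,
    read_map,
    segment_map,
    write_map,
)
from helixtrace.synthetic_data import MapSpec


class TestIO:
    def test_roundtrip_bit_exact(self, tmp_path, bundle_map):
        path = tmp_path / "map.mrc"
        write_map(bundle_map, path)
        back = read_map(path)
        assert np.array_equal(back.grid, bundle_map.grid)
        assert back.voxel_size == pytest.approx(bundle_map.voxel_size, abs=1e-6)
        assert np.allclose(back.origin, bundle_map.origin, atol=1e-5)

    def test_anisotropic_voxels_rejected(self, tmp_path):
        import gemmi

        ccp4 = gemmi.Ccp4Map()
        data = np.zeros((8, 8, 8), dtype=np.float32)
        ccp4.grid = gemmi.FloatGrid(data)
        ccp4.grid.unit_cell = gemmi.UnitCell(8.0, 16.0, 8.0, 90, 90, 90)
        ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
        ccp4.update_ccp4_header()
        path = tmp_path / "aniso.mrc"
        ccp4.write_ccp4_map(str(path))
        with pytest.raises(ValueError, match="anisotropic"):
            read_map(path)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            DensityMap(np.zeros((1, 4, 4)), 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            DensityMap(np.zeros((4, 4, 4)), -1.0, np.zeros(3))


class TestRigidTransform:
    def test_orthogonality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_composes_to_identity(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -10, 35], degrees=True).as_matrix()
        t = RigidTransform(rot, np.array([1.0, -2.0, 3.0]))
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


class TestSegmentMap:
    def test_full_box_mask_is_identity(self, bundle_map):
        out = segment_map(bundle_map, np.ones(bundle_map.shape, dtype=bool))
        assert np.array_equal(out.grid, bundle_map.grid)

    def test_empty_sphere_rejected(self, bundle_map):
        with pytest.raises(ValueError, match="intersect"):
            segment_map(bundle_map, ("sphere", bundle_map.origin - 100.0, 1e-4))

    def test_crop_then_restore(self, bundle_map):
        centre = bundle_map.centre
        cropped = segment_map(bundle_map, ("sphere", centre, 10.0), crop=True)
        assert cropped.grid.shape <= bundle_map.grid.shape
        # inside the mask values survive; the crop origin tracks the cut
        idx = np.indices(cropped.shape).reshape(3, -1).T
        world = cropped.index_to_world(idx)
        inside = np.linalg.norm(world - centre, axis=1) <= 10.0
        orig_idx = np.round(bundle_map.world_to_index(world)).astype(int)
        orig = bundle_map.grid[orig_idx[:, 0], orig_idx[:, 1], orig_idx[:, 2]]
        assert np.allclose(cropped.grid.reshape(-1)[inside], orig[inside], atol=1e-6)
        assert np.all(cropped.grid.reshape(-1)[~inside] == 0)


class TestAlign:
    def test_identity_alignment(self, bundle_map):
        t, aligned, corr = align_maps(bundle_map, bundle_map,
                                      coarse_step=15, max_angle=20)
        assert corr == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-3)

    def test_constant_map_rejected(self):
        flat = DensityMap(np.ones((16, 16, 16)), 1.0, np.zeros(3))
        with pytest.raises(ValueError, match="constant"):
            align_maps(flat, flat)

    def test_translation_recovered(self, small_bundle):
        spec = MapSpec(box_edge=40)
        fixed = sd.render_map(small_bundle.model, spec)
        shifted = DensityMap(np.roll(fixed.grid, 3, axis=0), fixed.voxel_size,
                             fixed.origin)
        t, _, corr = align_maps(shifted, fixed, coarse_step=10, max_angle=1e-6)
        shift_vox = (t.translation + t.rotation @ shifted.centre - fixed.centre) \
            / fixed.voxel_size
        assert abs(shift_vox[0] + 3) < 0.5 and np.all(np.abs(shift_vox[1:]) < 0.5)
        assert corr > 0.95

    def test_known_rotation_recovered(self, small_bundle):
        from scipy.spatial.transform import Rotation

        centre = small_bundle.model.ca.mean(axis=0)
        maps, _ = sd.make_state_ensemble(small_bundle, {1, 2, 3, 4},
                                         [0.0, 12.0], centre, [0, 0, 1],
                                         MapSpec())
        t, _, corr = align_maps(maps[1], maps[0], coarse_step=8, max_angle=25)
        angle = np.linalg.norm(
            Rotation.from_matrix(t.rotation).as_rotvec(degrees=True))
        assert angle == pytest.approx(12.0, abs=1.0)
        assert corr > 0.9

    def test_self_consistency(self, small_bundle):
        from scipy.spatial.transform import Rotation

        centre = small_bundle.model.ca.mean(axis=0)
        maps, _ = sd.make_state_ensemble(small_bundle, {1, 2, 3, 4},
                                         [0.0, 9.0], centre, [0, 0, 1],
                                         MapSpec())
        _, aligned, _ = align_maps(maps[1], maps[0], coarse_step=8, max_angle=20)
        t2, _, _ = align_maps(aligned, maps[0], coarse_step=5, max_angle=8)
        residual = np.linalg.norm(
            Rotation.from_matrix(t2.rotation).as_rotvec(degrees=True))
        assert residual < 0.5


class TestAverage:
    def test_identical_maps_zero_variance(self, bundle_map):
        mean, var = average_maps([bundle_map, bundle_map, bundle_map])
        assert np.allclose(mean.grid, bundle_map.grid, atol=1e-6)
        assert np.allclose(var.grid, 0.0, atol=1e-9)

    def test_requires_two_maps(self, bundle_map):
        with pytest.raises(ValueError):
            average_maps([bundle_map])

    def test_noise_reduction_sqrt_n(self, small_bundle):
        spec = MapSpec(box_edge=40, noise_sigma=0.2)
        maps = [sd.render_map(small_bundle.model, spec, rng_seed=s)
                for s in range(7)]
        mean, _ = average_maps(maps)
        corner = (slice(0, 8), slice(0, 8), slice(0, 8))  # signal-free region
        single = float(np.mean([m.grid[corner].std() for m in maps]))
        reduction = single / float(mean.grid[corner].std())
        assert reduction == pytest.approx(np.sqrt(7), rel=0.1)


class TestFsc:
    def test_self_fsc_is_one(self, bundle_map):
        curve = fsc(bundle_map, bundle_map)
        assert np.allclose(curve.correlations, 1.0, atol=1e-6)
        assert curve.correlations[0] == pytest.approx(1.0)

    def test_symmetric_and_bounded(self, small_bundle):
        a = sd.render_map(small_bundle.model, MapSpec(box_edge=32, noise_sigma=0.1), 1)
        b = sd.render_map(small_bundle.model, MapSpec(box_edge=32, noise_sigma=0.1), 2)
        ab = fsc(a, b)
        ba = fsc(b, a)
        assert np.allclose(ab.correlations, ba.correlations, atol=1e-9)
        assert np.all(np.abs(ab.correlations) <= 1.0 + 1e-9)

    def test_pure_noise_decorrelated(self):
        rng = np.random.default_rng(0)
        a = DensityMap(rng.normal(size=(48, 48, 48)), 1.64, np.zeros(3))
        b = DensityMap(rng.normal(size=(48, 48, 48)), 1.64, np.zeros(3))
        curve = fsc(a, b)
        big = curve.n_coefficients >= 1000
        assert np.abs(curve.correlations[big]).max() < 0.1
        assert abs(curve.correlations[big].mean()) < 0.02

    def test_grid_mismatch_rejected(self, bundle_map):
        other = DensityMap(np.zeros((8, 8, 8)), bundle_map.voxel_size, np.zeros(3))
        with pytest.raises(ValueError):
            fsc(bundle_map, other)
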