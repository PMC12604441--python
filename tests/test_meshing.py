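"""Surface extraction, mirroring, filtering, smoothing, ICP and shaft cut."""

import numpy as np
import pytest
import trimesh

import kneeshape as ks
from kneeshape.meshing import RigidTransform
from kneeshape.volumes import LabelVolume

from conftest import rotation_z


class TestRigidTransform:
    def test_rejects_scaling_and_reflection(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(2.0 * np.eye(3), np.zeros(3))
        with pytest.raises(ValueError, match="eflection"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        t = RigidTransform(rotation_z(30), [1.0, -2.0, 3.0])
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts)
        assert np.allclose(t.compose(t.inverse()).matrix, np.eye(4), atol=1e-12)


class TestMarchingCubes:
    def test_sphere_surface_area_and_volume(self, sphere_volume):
        mesh = ks.marching_cubes(sphere_volume, 1)
        assert mesh.is_watertight
        assert abs(mesh.area / (4.0 * np.pi * 100.0) - 1) < 0.03
        assert abs(mesh.volume / (4.0 / 3.0 * np.pi * 1000.0) - 1) < 0.05

    def test_single_voxel_gives_small_closed_octahedron(self):
        grid = np.zeros((5, 5, 5), np.int16)
        grid[2, 2, 2] = 1
        mesh = ks.marching_cubes(LabelVolume(grid, spacing=(0.7,) * 3), 1)
        assert mesh.is_watertight and mesh.volume > 0
        # marching cubes turns one voxel into its dual octahedron: s^3/6
        assert abs(mesh.volume / (0.7 ** 3 / 6.0) - 1) < 0.2

    def test_absent_class_is_an_error(self, sphere_volume):
        with pytest.raises(ValueError, match="absent"):
            ks.marching_cubes(sphere_volume, 3)


class TestMirrorToLeft:
    def test_left_mesh_unchanged(self, patella):
        out = ks.mirror_to_left(patella, "left")
        assert np.array_equal(out.vertices, patella.vertices)

    def test_involution(self, bumpy_shape):
        twice = ks.mirror_to_left(ks.mirror_to_left(bumpy_shape, "right"), "right")
        assert np.allclose(twice.vertices, bumpy_shape.vertices, atol=1e-12)

    def test_normals_still_outward(self, patella):
        assert ks.mirror_to_left(patella, "right").volume > 0

    def test_chirality_not_reachable_by_rotation(self, bumpy_shape):
        mirrored = ks.mirror_to_left(bumpy_shape, "right")
        _, _, resid = ks.icp_align(mirrored, bumpy_shape)
        assert resid > 0.05    # a reflection cannot be undone rigidly

    def test_unknown_side_rejected(self, patella):
        with pytest.raises(ValueError, match="side"):
            ks.mirror_to_left(patella, "lateral")


class TestKeepLargestComponent:
    def test_single_component_unchanged(self, patella):
        assert len(ks.keep_largest_component(patella).faces) == len(patella.faces)

    def test_loose_body_removed(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        cube = trimesh.creation.box(extents=(2, 2, 2))
        cube.apply_translation([40.0, 0.0, 0.0])
        merged = trimesh.util.concatenate([sphere, cube])
        kept = ks.keep_largest_component(merged)
        assert len(kept.faces) == len(sphere.faces)
        assert kept.bounds[1, 0] < 20

    def test_face_tie_broken_by_volume(self):
        a = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        b = trimesh.creation.icosphere(subdivisions=2, radius=6.0)
        b.apply_translation([30.0, 0.0, 0.0])
        kept = ks.keep_largest_component(trimesh.util.concatenate([a, b]))
        assert kept.bounds[0, 0] > 20    # the larger-volume copy survives

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ks.keep_largest_component(trimesh.Trimesh())


class TestSmoothAndRemesh:
    def test_zero_rounds_is_identity(self, patella):
        out = ks.smooth_and_remesh(patella, rounds=0)
        assert np.array_equal(out.vertices, patella.vertices)

    def test_uniform_icosphere_volume_preserved(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        out = ks.smooth_and_remesh(ico)
        assert abs(out.volume / ico.volume - 1) < 0.01

    def test_noisy_sphere_regularized(self):
        rng = np.random.default_rng(0)
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        noisy = trimesh.Trimesh(ico.vertices + rng.normal(0, 0.3, ico.vertices.shape),
                                ico.faces, process=False)
        out = ks.smooth_and_remesh(noisy, rounds=2, smooth_iters=5)
        assert out.is_watertight
        rad = lambda m: np.linalg.norm(m.vertices, axis=1).std()
        assert rad(out) < rad(noisy)
        cv = lambda m: m.edges_unique_length.std() / m.edges_unique_length.mean()
        assert cv(out) < cv(noisy)
        assert abs(out.volume / noisy.volume - 1) < 0.05


class TestICP:
    def test_identity_when_already_aligned(self, bumpy_shape):
        t, _, d = ks.icp_align(bumpy_shape, bumpy_shape)
        assert d < 1e-9
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_recovers_known_rotation_translation(self, bumpy_shape):
        true = RigidTransform(rotation_z(10.0), [5.0, 3.0, 1.0])
        moving = trimesh.Trimesh(true.inverse().apply(bumpy_shape.vertices),
                                 bumpy_shape.faces, process=False)
        t, _, d = ks.icp_align(moving, bumpy_shape)
        cos = (np.trace(t.rotation @ true.rotation.T) - 1.0) / 2.0
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.5
        assert np.linalg.norm(t.translation - true.translation) < 0.1

    def test_noise_floor(self, bumpy_shape):
        rng = np.random.default_rng(1)
        noisy = trimesh.Trimesh(
            bumpy_shape.vertices + rng.normal(0, 0.1, bumpy_shape.vertices.shape),
            bumpy_shape.faces, process=False)
        _, _, d = ks.icp_align(noisy, bumpy_shape, init="identity")
        assert d < 0.2

    def test_degenerate_points_rejected(self, patella):
        line = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="ollinear|degenerate"):
            ks.icp_align(line, patella)


class TestCutFemoralShaft:
    def test_cut_extent_and_closure(self):
        femur = ks.femur_template()
        cut = ks.cut_femoral_shaft(femur, keep_length=70.0)
        extent = cut.bounds[1, 1] - cut.bounds[0, 1]
        assert abs(extent - 70.0) <= 0.7
        assert cut.is_watertight and cut.volume > 0

    def test_short_mesh_returned_unchanged(self, patella):
        out = ks.cut_femoral_shaft(patella, keep_length=70.0)
        assert np.array_equal(out.vertices, patella.vertices)

    def test_idempotent(self):
        femur = ks.femur_template()
        once = ks.cut_femoral_shaft(femur, keep_length=70.0)
        twice = ks.cut_femoral_shaft(once, keep_length=70.0)
        assert abs(twice.volume - once.volume) < 1e-9
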