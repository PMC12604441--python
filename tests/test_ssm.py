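"""Groupwise alignment, correspondence and the PCA shape model."""

import numpy as np
import pytest
import trimesh
from scipy.linalg import subspace_angles

import kneeshape as ks
from kneeshape.meshing import RigidTransform
from kneeshape.ssm import StatisticalShapeModel, choose_template

from conftest import rotation_z


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return RigidTransform(r, rng.normal(scale=10.0, size=3))


class TestGroupwiseAlign:
    def test_copies_under_random_rigid_transforms_collapse(self, small_template):
        rng = np.random.default_rng(0)
        base = small_template.vertices
        shapes = [random_rigid(rng).apply(base) for _ in range(8)]
        aligned, transforms = ks.groupwise_align(shapes)
        stack = np.stack(aligned)
        rmsd = np.sqrt(((stack - stack.mean(0)) ** 2).sum(-1).mean())
        assert rmsd < 1e-6
        for t in transforms:
            assert np.linalg.det(t.rotation) > 0

    def test_already_aligned_population_untouched(self, small_template):
        rng = np.random.default_rng(1)
        shapes = [small_template.vertices + rng.normal(0, 0.01, (42, 3))
                  for _ in range(5)]
        centered = [s - s.mean(0) for s in shapes]
        _, transforms = ks.groupwise_align(centered, max_iter=1)
        for t in transforms:
            assert np.allclose(t.rotation, np.eye(3), atol=1e-2)

    def test_order_invariance_of_mean(self, small_template):
        rng = np.random.default_rng(2)
        shapes = [random_rigid(rng).apply(small_template.vertices)
                  for _ in range(6)]
        a1, _ = ks.groupwise_align(shapes)
        perm = [3, 0, 5, 1, 4, 2]
        a2, _ = ks.groupwise_align([shapes[i] for i in perm])
        m1 = np.mean(a1, axis=0)
        m2 = np.mean(a2, axis=0)
        assert np.abs(m1 - m2).max() < 1e-6

    def test_needs_two_shapes(self, small_template):
        with pytest.raises(ValueError, match="2 shapes"):
            ks.groupwise_align([small_template.vertices])


class TestCorrespond:
    def test_identity_when_shape_is_template(self, patella):
        out = ks.correspond([patella], template=patella.vertices)
        assert np.abs(out[0] - patella.vertices).max() < 1e-9

    def test_scaled_sphere_radial_closest_points(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        big = trimesh.Trimesh(sphere.vertices * 1.1, sphere.faces, process=False)
        out = ks.correspond([big], template=sphere.vertices)
        radii = np.linalg.norm(out[0], axis=1)
        assert np.allclose(radii, 11.0, atol=0.05)

    def test_point_count_matches_template(self, patella, small_template):
        out = ks.correspond([patella, patella], template=small_template.vertices)
        assert out.shape == (2, len(small_template.vertices), 3)

    def test_template_choice_is_medoid(self, small_template):
        base = small_template.vertices
        shapes = [base, base + 0.001, base + np.array([5.0, 0, 0])]
        assert choose_template(shapes) in (0, 1)


class TestShapeModel:
    def test_recovers_planted_modes_and_spectrum(self, small_template):
        truth = ks.make_truth_model(small_template, 3, [9, 4, 1],
                                    residual_sd=0.05, seed=0)
        cohort = ks.generate_cohort(100, seed=100)
        shapes, _ = ks.sample_shapes(truth, cohort,
                                     ks.EffectSpec({}, within_subject_rho=0.0),
                                     seed=200)
        model = StatisticalShapeModel().fit(shapes)
        ang = np.rad2deg(subspace_angles(model.modes_[:, :3], truth.true_modes))
        assert ang.max() < 5.0

    def test_matches_bruteforce_eigendecomposition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 60))       # 10 shapes x 20 points
        model = StatisticalShapeModel().fit(x)
        ref = np.linalg.eigvalsh(np.cov(x.T))[::-1][: len(model.eigenvalues_)]
        assert np.abs(model.eigenvalues_ - ref).max() < 1e-9 * ref[0]

    def test_rank_bound_with_three_shapes(self):
        rng = np.random.default_rng(4)
        model = StatisticalShapeModel().fit(rng.normal(size=(3, 30)))
        assert (model.eigenvalues_ > 1e-12).sum() <= 2

    def test_spectrum_sorted_and_fractions_normalized(self, small_template):
        truth = ks.make_truth_model(small_template, 3, [9, 4, 1], seed=0)
        shapes, _ = ks.sample_shapes(truth, ks.generate_cohort(30, seed=5), seed=6)
        model = StatisticalShapeModel().fit(shapes)
        assert (np.diff(model.eigenvalues_) <= 1e-12).all()
        assert abs(model.explained_fraction_.sum() - 1.0) < 1e-9

    def test_full_reconstruction_of_training_shapes(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 24))
        model = StatisticalShapeModel().fit(x)
        back = model.inverse_transform(model.transform(x))
        assert np.abs(back - x).max() < 1e-6

    def test_rigid_motion_of_population_leaves_spectrum(self, small_template):
        truth = ks.make_truth_model(small_template, 2, [4, 1], seed=1)
        shapes, _ = ks.sample_shapes(truth, ks.generate_cohort(40, seed=7), seed=8)
        m1 = StatisticalShapeModel().fit(shapes)
        t = RigidTransform(rotation_z(25.0), [3.0, -1.0, 2.0])
        moved = np.stack([t.apply(s) for s in shapes])
        m2 = StatisticalShapeModel().fit(moved)
        k = min(10, len(m1.eigenvalues_))
        rel = np.abs(m2.eigenvalues_[:k] - m1.eigenvalues_[:k]) / m1.eigenvalues_[0]
        assert rel.max() < 1e-6
        assert np.allclose(m2.explained_fraction_[:k], m1.explained_fraction_[:k],
                           atol=1e-6)


@pytest.fixture(scope="module")
def fitted(small_template):
    truth = ks.make_truth_model(small_template, 3, [9, 4, 1],
                                residual_sd=0.02, seed=2)
    shapes, _ = ks.sample_shapes(truth, ks.generate_cohort(60, seed=9), seed=10)
    return StatisticalShapeModel().fit(shapes), shapes


class TestScoresAndReconstruction:
    def test_mean_projects_to_zero(self, fitted):
        model, _ = fitted
        assert np.abs(ks.project(model.mean_, model)).max() < 1e-9

    def test_training_scores_standardized(self, fitted):
        model, shapes = fitted
        s = model.transform(shapes)
        nz = model.eigenvalues_ > 1e-10 * model.eigenvalues_[0]
        assert np.abs(s.mean(0)[nz]).max() < 1e-6
        assert np.abs(s.std(0, ddof=1)[nz] - 1.0).max() < 1e-3

    def test_score_roundtrip(self, fitted):
        model, _ = fitted
        e = np.zeros(len(model.eigenvalues_))
        e[1] = 3.0
        back = ks.project(model.inverse_transform(e), model)
        assert abs(back[1] - 3.0) < 1e-9
        assert np.abs(np.delete(back, 1)).max() < 1e-9

    def test_plus_minus_symmetric_about_mean(self, fitted):
        model, _ = fitted
        e = np.zeros(len(model.eigenvalues_))
        e[0] = 3.0
        mid = 0.5 * (model.inverse_transform(e) + model.inverse_transform(-e))
        assert np.abs(mid - model.mean_).max() < 1e-9

    def test_displacement_norm_is_score_times_sqrt_lambda(self, fitted):
        model, _ = fitted
        e = np.zeros(len(model.eigenvalues_))
        e[2] = 2.5
        norm = np.linalg.norm(model.inverse_transform(e) - model.mean_)
        assert abs(norm - 2.5 * np.sqrt(model.eigenvalues_[2])) < 1e-9

    def test_overlong_score_vector_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="longer"):
            model.inverse_transform(np.zeros(len(model.eigenvalues_) + 1))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, shapes = fitted
        model.save(tmp_path / "model", metadata={"bone": "patella"})
        back = StatisticalShapeModel.load(tmp_path / "model")
        assert np.allclose(back.transform(shapes[:4]), model.transform(shapes[:4]))


class TestSelectionAndDistanceMaps:
    def test_select_modes_fraction_rule(self):
        fracs = [0.50, 0.30, 0.012, 0.009, 0.005]
        assert ks.select_modes(fracs, 0.01).tolist() == [0, 1, 2]
        assert ks.select_modes(fracs, 1.1).size == 0

    def test_pure_inflation_mode_map(self):
        # mode = uniform radial displacement d per SD on a sphere
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        v = sphere.vertices
        direction = (v / np.linalg.norm(v, axis=1, keepdims=True)).ravel()
        direction /= np.linalg.norm(direction)
        model = StatisticalShapeModel()
        model.mean_ = v.ravel()
        model.modes_ = direction[:, None]
        model.eigenvalues_ = np.array([4.0])
        model.explained_fraction_ = np.array([1.0])
        model.n_points_, model.n_samples_ = len(v), 100
        dm = model.distance_map(0, sd=3.0, faces=sphere.faces)
        d_per_vertex = 3.0 * 2.0 / np.sqrt(len(v))   # 3 sd * sqrt(4) * |unit|/sqrtP
        assert np.allclose(dm["plus"], d_per_vertex, rtol=1e-6)
        assert np.allclose(dm["minus"], -d_per_vertex, rtol=1e-6)  # signed inward

    def test_distance_bounded_by_mode_norm(self, small_template):
        truth = ks.make_truth_model(small_template, 2, [4, 1], seed=3)
        shapes, _ = ks.sample_shapes(truth, ks.generate_cohort(30, seed=11), seed=12)
        model = StatisticalShapeModel().fit(shapes)
        dm = model.distance_map(0, sd=3.0)
        disp = model.modes_[:, 0].reshape(-1, 3)
        bound = 3.0 * np.sqrt(model.eigenvalues_[0]) * np.linalg.norm(disp, axis=1).max()
        assert np.abs(dm["plus"]).max() <= bound + 1e-9
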