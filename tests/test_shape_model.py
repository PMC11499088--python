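"""Particle correspondence and the PCA point-distribution model."""

import numpy as np
import pytest

from morphodetail.errors import CorrespondenceError
from morphodetail.mesh_core import SurfaceLocator, normalize_volume, sample_surface
from morphodetail.registration import RigidTransform, icp, coarse_align
from morphodetail.shape_model import (EPSILON_SURFACE, CorrespondenceSet,
                                      establish_correspondence, fit_pca,
                                      reconstruct, sample_shape)


@pytest.fixture(scope="module")
def cohort_correspondence(request):
    small_cohort = request.getfixturevalue("small_cohort")
    meshes, _ = small_cohort
    corr = establish_correspondence(meshes, n_particles=64, n_init=16, seed=0)
    return meshes, corr


def _random_correspondence(rng, n_shapes=10, k=20) -> CorrespondenceSet:
    pts = rng.normal(size=(n_shapes, k, 3))
    return CorrespondenceSet(points=pts,
                             shape_ids=[f"s{i}" for i in range(n_shapes)])


class TestEstablishCorrespondence:
    def test_identical_meshes_get_identical_particles(self, bent_mesh):
        meshes = [normalize_volume(bent_mesh).copy() for _ in range(4)]
        corr = establish_correspondence(meshes, n_particles=64, n_init=16,
                                        seed=0)
        dev = np.abs(corr.points - corr.points[0]).max()
        assert dev < 1e-6

    def test_particles_on_surface(self, cohort_correspondence):
        meshes, corr = cohort_correspondence
        for mesh, pts in zip(meshes, corr.points):
            _, d, _ = SurfaceLocator(mesh).closest(pts)
            assert d.max() <= EPSILON_SURFACE

    def test_rigidly_registered_copy_agrees(self, bent_mesh, rng):
        """A rigidly moved copy registered back gets particles within the
        surface tolerance of the original's particles."""
        a = normalize_volume(bent_mesh)
        b = a.copy()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation
        g = RigidTransform(Rotation.from_rotvec(0.3 * axis).as_matrix(),
                           np.array([4.0, -2.0, 7.0]))
        b.vertices = g.apply(b.vertices)
        t, _ = icp(b, a, coarse_align(b, a), seed=0)
        b.vertices = t.apply(b.vertices)
        corr = establish_correspondence([a, b], n_particles=64, n_init=16,
                                        seed=0)
        dev = np.linalg.norm(corr.points[0] - corr.points[1], axis=1)
        assert np.median(dev) < 0.5

    def test_split_count_doubling(self, small_cohort):
        meshes, _ = small_cohort
        corr = establish_correspondence(meshes[:3], n_particles=128, n_init=16,
                                        seed=0)
        assert corr.n_particles == 128

    def test_invalid_particle_counts_rejected(self, small_cohort):
        meshes, _ = small_cohort
        with pytest.raises(CorrespondenceError):
            establish_correspondence(meshes[:2], n_particles=100, n_init=16)

    def test_coverage_improves_with_particle_count(self, small_cohort):
        """Max surface-to-nearest-particle distance shrinks when the
        particle count doubles."""
        meshes, _ = small_cohort
        mesh = meshes[0]
        cover = {}
        for k in (32, 64):
            corr = establish_correspondence(meshes[:2], n_particles=k,
                                            n_init=16, seed=0)
            samples = sample_surface(mesh, 3000, seed=5).points
            from scipy.spatial import cKDTree
            d, _ = cKDTree(corr.points[0]).query(samples)
            cover[k] = d.max()
        assert cover[64] < cover[32]


class TestFitPCA:
    def test_two_shape_analytic_case(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=(5, 3))
        x2 = rng.normal(size=(5, 3))
        corr = CorrespondenceSet(points=np.stack([x1, x2]),
                                 shape_ids=["a", "b"])
        model = fit_pca(corr)
        nonzero = model.eigenvalues[model.eigenvalues > 1e-12]
        assert len(nonzero) == 1
        expected = np.linalg.norm((x1 - x2).ravel()) ** 2 / 2.0
        assert np.isclose(nonzero[0], expected, rtol=1e-10)
        assert np.allclose(model.mean, (x1 + x2).ravel() / 2.0)

    def test_matches_dense_covariance_eigendecomposition(self, rng):
        corr = _random_correspondence(rng)
        model = fit_pca(corr)
        x = corr.to_matrix()
        cov = np.cov(x.T, ddof=1)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1][:model.n_modes]
        assert np.allclose(model.eigenvalues, oracle, rtol=1e-8, atol=1e-10)

    def test_full_mode_reconstruction_is_exact(self, rng):
        corr = _random_correspondence(rng)
        model = fit_pca(corr)
        for j in range(corr.n_shapes):
            x = corr.to_matrix()[j]
            assert np.linalg.norm(reconstruct(model, x, model.n_modes) - x) \
                < 1e-8

    def test_scores_zero_mean_and_orthonormal_modes(self, rng):
        corr = _random_correspondence(rng)
        model = fit_pca(corr)
        assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-10)
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(model.n_modes), atol=1e-8)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        corr = _random_correspondence(rng)
        model = fit_pca(corr)
        x = corr.to_matrix()
        total = ((x - x.mean(axis=0)) ** 2).sum() / (corr.n_shapes - 1)
        assert np.isclose(model.eigenvalues.sum(), total, rtol=1e-9)

    def test_translation_equivariance(self, rng):
        corr = _random_correspondence(rng)
        shift = np.array([3.0, -1.0, 2.0])
        moved = CorrespondenceSet(points=corr.points + shift,
                                  shape_ids=corr.shape_ids)
        a, b = fit_pca(corr), fit_pca(moved)
        assert np.allclose(b.mean.reshape(-1, 3),
                           a.mean.reshape(-1, 3) + shift, atol=1e-9)
        assert np.allclose(a.eigenvalues, b.eigenvalues, rtol=1e-9)


class TestReconstructAndSample:
    def test_reconstruction_error_non_increasing_in_modes(self, rng):
        corr = _random_correspondence(rng)
        model = fit_pca(corr)
        target = rng.normal(size=corr.to_matrix().shape[1])
        errors = [np.linalg.norm(reconstruct(model, target, m) - target)
                  for m in range(1, model.n_modes + 1)]
        assert all(a >= b - 1e-10 for a, b in zip(errors, errors[1:]))

    def test_zero_modes_disallowed(self, rng):
        model = fit_pca(_random_correspondence(rng))
        with pytest.raises(ValueError):
            reconstruct(model, model.mean, 0)
        with pytest.raises(ValueError):
            sample_shape(model, 0)

    def test_zero_draw_gives_mean(self, rng):
        model = fit_pca(_random_correspondence(rng))
        draw = sample_shape(model, 3, z=np.zeros(3))
        assert np.allclose(draw, model.mean)

    def test_same_seed_same_draw(self, rng):
        model = fit_pca(_random_correspondence(rng))
        assert np.array_equal(sample_shape(model, 4, seed=9),
                              sample_shape(model, 4, seed=9))

    def test_draw_covariance_matches_eigenvalues(self, rng):
        model = fit_pca(_random_correspondence(rng, n_shapes=12, k=6))
        n_modes = 3
        draws = np.stack([sample_shape(model, n_modes, seed=s)
                          for s in range(10000)])
        centered = draws - model.mean
        coeffs = centered @ model.eigenvectors[:, :n_modes]
        sample_var = coeffs.var(axis=0, ddof=1)
        assert np.allclose(sample_var, model.eigenvalues[:n_modes], rtol=0.05)


class TestSerialization:
    def test_correspondence_round_trip(self, rng, tmp_path):
        corr = _random_correspondence(rng, n_shapes=3, k=5)
        corr.save(tmp_path / "corr")
        back = CorrespondenceSet.load(tmp_path / "corr")
        assert back.shape_ids == corr.shape_ids
        assert np.allclose(back.points, corr.points, atol=1e-9)

    def test_model_round_trip(self, rng, tmp_path):
        from morphodetail.shape_model import ShapeModel
        model = fit_pca(_random_correspondence(rng, n_shapes=4, k=5))
        model.save(tmp_path / "model")
        back = ShapeModel.load(tmp_path / "model")
        assert np.allclose(back.eigenvalues, model.eigenvalues)
        assert np.allclose(back.eigenvectors, model.eigenvectors, atol=1e-9)
        assert back.n_shapes == model.n_shapes
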