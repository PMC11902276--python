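import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ensdyn import io, pca


class TestCovariance:
    def test_identical_frames_give_zero_matrix(self, toy_model):
        ens = io.Ensemble(np.stack([toy_model.coordinates] * 3))
        cov = pca.covariance(ens)
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-18)

    def test_two_point_one_dimensional_variance(self):
        frames = np.zeros((2, 1, 3))
        frames[0, 0, 0] = 1.0
        frames[1, 0, 0] = -1.0
        cov = pca.covariance(io.Ensemble(frames), fit=False)
        assert cov.matrix[0, 0] == pytest.approx(1.0)
        assert np.abs(cov.matrix).sum() == pytest.approx(1.0)

    def test_population_divisor(self):
        # three 1-D samples {0, 0, 3}: population variance = 2, not 3
        frames = np.zeros((3, 1, 3))
        frames[2, 0, 0] = 3.0
        cov = pca.covariance(io.Ensemble(frames), fit=False)
        assert cov.matrix[0, 0] == pytest.approx(2.0)

    def test_rigid_transform_invariance_with_fit(self, anm_ensemble, rng):
        # transform the whole trajectory rigidly; fitting anchored to a fixed
        # reference must reproduce the same covariance elementwise
        ens, _ = anm_ensemble
        sub = io.Ensemble(ens.coords[:100])
        ref = sub.coords.mean(axis=0)
        R = Rotation.random(random_state=7).as_matrix()
        shift = rng.normal(scale=3.0, size=3)
        moved = sub.coords @ R.T + shift
        c1 = pca.covariance(sub, reference=ref).matrix
        c2 = pca.covariance(io.Ensemble(moved), reference=ref).matrix
        np.testing.assert_allclose(c1, c2, atol=1e-6)


class TestPCA:
    def test_eigen_identities(self, anm_ensemble):
        ens, _ = anm_ensemble
        cov = pca.covariance(ens)
        result = pca.pca(cov, ens)
        assert result.eigenvalues.sum() == pytest.approx(
            np.trace(cov.matrix), rel=1e-6
        )
        assert result.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(result.eigenvectors, axis=0), 1.0, atol=1e-9
        )
        # projection variance equals the eigenvalue (population divisor)
        proj_var = result.projections.var(axis=0, ddof=0)
        keep = result.eigenvalues > 1e-10 * result.eigenvalues[0]
        np.testing.assert_allclose(
            proj_var[keep], result.eigenvalues[keep], rtol=1e-6, atol=1e-12
        )

    def test_matches_independent_dense_solver(self, rng):
        A = rng.normal(size=(12, 12))
        spd = A @ A.T + 0.5 * np.eye(12)
        cov = pca.CovarianceMatrix(spd, mean_structure=np.zeros((4, 3)),
                                   n_frames=10)
        result = pca.pca(cov)
        lam, vec = np.linalg.eig(spd)  # independent non-symmetric solver
        order = np.argsort(lam.real)[::-1]
        np.testing.assert_allclose(result.eigenvalues, lam.real[order],
                                   atol=1e-8)
        for k in range(12):
            v = vec[:, order[k]].real
            v = v / np.linalg.norm(v)
            dot = abs(np.dot(v, result.eigenvectors[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_equal_eigenvalues_give_equal_fractions(self):
        cov = pca.CovarianceMatrix(np.eye(3) * 2.0,
                                   mean_structure=np.zeros((1, 3)), n_frames=5)
        result = pca.pca(cov)
        np.testing.assert_allclose(result.variance_fractions, 1.0 / 3.0)

    def test_reconstruction_from_all_components(self, anm_ensemble):
        ens, _ = anm_ensemble
        sub = io.Ensemble(ens.coords[:50])
        cov = pca.covariance(sub)
        result = pca.pca(cov, sub)
        recon = result.projections @ result.eigenvectors.T
        from ensdyn.metrics import superpose_frames

        fitted = superpose_frames(sub.coords, cov.mean_structure)
        centered = fitted.reshape(50, -1) - cov.mean_structure.ravel()
        np.testing.assert_allclose(recon, centered, atol=1e-6)


class TestCosineContent:
    def test_half_period_cosine_is_one(self):
        F = 10000
        t = np.arange(F)
        c = pca.cosine_content(np.cos(np.pi * t / F))
        assert c == pytest.approx(1.0, abs=10.0 / F)

    def test_full_period_cosine_is_orthogonal(self):
        F = 10000
        t = np.arange(F)
        c = pca.cosine_content(np.cos(2 * np.pi * t / F))
        assert c < 10.0 / F

    def test_white_noise_passes_threshold(self, rng):
        c = pca.cosine_content(rng.standard_normal(10000))
        assert c < 0.1

    def test_all_zero_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert pca.cosine_content(np.zeros(10)) == 0.0


def _result_with_cosines(cosines):
    n = len(cosines)
    return pca.PCAResult(
        eigenvalues=np.arange(n, 0, -1, dtype=float),
        eigenvectors=np.eye(n),
        variance_fractions=np.full(n, 1.0 / n),
        cosine_contents=np.asarray(cosines, dtype=float),
        projections=None,
    )


class TestSelectPcs:
    def test_all_pass_gives_first_two(self):
        assert pca.select_pcs(_result_with_cosines([0.01] * 20)) == (0, 1)

    def test_failing_leader_is_skipped(self):
        cos = [0.5] + [0.02] * 19
        assert pca.select_pcs(_result_with_cosines(cos)) == (1, 2)

    def test_sparse_passes_pick_highest_variance_pair(self):
        cos = np.full(20, 0.9)
        cos[[3, 7, 9]] = 0.05
        assert pca.select_pcs(_result_with_cosines(cos)) == (3, 7)

    def test_fewer_than_two_passing_is_an_error(self):
        with pytest.raises(ValueError, match="sampling"):
            pca.select_pcs(_result_with_cosines([0.9] * 20))


class TestFreeEnergyLandscape:
    def test_uniform_occupancy_is_flat(self):
        # 4 bins along each axis, every bin equally occupied
        vals = np.repeat(np.arange(4), 4) + 0.5
        a = np.tile(vals, 4)
        b = np.repeat(np.arange(4).repeat(4), 4) + 0.5
        a = np.concatenate([a] * 2)
        b = np.concatenate([b, b])
        fel = pca.free_energy_landscape(a, b, n_bins=4)
        assert fel.mask.sum() == 0
        np.testing.assert_allclose(fel.free_energy.filled(0), 0.0, atol=1e-12)

    def test_delta_distribution_masks_everything_else(self):
        a = np.zeros(64)
        b = np.zeros(64)
        fel = pca.free_energy_landscape(a, b, n_bins=8)
        assert fel.free_energy.count() == 1
        assert fel.free_energy.compressed()[0] == 0.0

    def test_occupied_minimum_is_exactly_zero(self, rng):
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000)
        fel = pca.free_energy_landscape(a, b)
        assert fel.free_energy.min() == 0.0
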