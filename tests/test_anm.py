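import numpy as np
import pytest

from ensdyn import anm, io
from ensdyn.anm import DisconnectedNetworkError


@pytest.fixture(scope="module")
def chain3():
    """Linear 3-node chain at 5 Å spacing; springs only between neighbours."""
    coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
    return anm.build_anm(coords, cutoff=6.0)


@pytest.fixture(scope="module")
def toy_anm(toy_model):
    return anm.build_anm(toy_model.coordinates, cutoff=12.0)


class TestBuildAnm:
    def test_two_node_closed_form(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        model = anm.build_anm(coords, cutoff=6.0, gamma=1.0)
        lam = model.eigenvalues
        nonzero = lam[np.abs(lam) > 1e-8 * lam.max()]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2.0)
        mode = model.eigenvectors[:, -1]
        expected = np.array([1, 0, 0, -1, 0, 0]) / np.sqrt(2)
        assert abs(np.dot(mode, expected)) == pytest.approx(1.0, abs=1e-9)

    def test_gamma_scales_eigenvalues(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        model = anm.build_anm(coords, cutoff=6.0, gamma=3.0)
        assert model.eigenvalues[-1] == pytest.approx(6.0)

    def test_block_row_sums_vanish(self, toy_anm):
        N = toy_anm.n_nodes
        H = toy_anm.hessian.reshape(N, 3, N, 3)
        np.testing.assert_allclose(H.sum(axis=2), 0.0, atol=1e-10)

    def test_chain_hessian_matches_hand_assembly(self, chain3):
        k = np.zeros((3, 3))
        k[0, 0] = 1.0  # spring along x at distance 5: d d^T / |d|^2 = e_x e_x^T
        H = np.zeros((9, 9))
        for i, j in [(0, 1), (1, 2)]:
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = -k
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = -k
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += k
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += k
        np.testing.assert_allclose(chain3.hessian, H, atol=1e-12)

    def test_connected_fixture_has_exactly_six_zero_modes(self, toy_anm):
        assert toy_anm.n_zero_modes == 6

    def test_disconnected_network_is_a_named_failure(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [100.0, 0, 0]])
        with pytest.raises(DisconnectedNetworkError):
            anm.build_anm(coords, cutoff=6.0)


class TestAnmCovariance:
    def test_all_modes_equal_pseudo_inverse(self, toy_anm):
        cov = anm.anm_covariance(toy_anm, n_modes=None)
        pinv = np.linalg.pinv(toy_anm.hessian, rcond=1e-10)
        np.testing.assert_allclose(cov, pinv, atol=1e-8)

    def test_pseudo_inverse_identity(self, toy_anm):
        cov = anm.anm_covariance(toy_anm, n_modes=None)
        H = toy_anm.hessian
        np.testing.assert_allclose(H @ cov @ H, H, atol=1e-6)

    def test_two_node_single_mode_closed_form(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        model = anm.build_anm(coords, cutoff=6.0)
        cov = anm.anm_covariance(model, n_modes=1)
        assert np.linalg.matrix_rank(cov, tol=1e-10) == 1
        assert np.trace(cov) == pytest.approx(0.5)  # 1/lambda = 1/2

    def test_too_many_modes_rejected(self, chain3):
        with pytest.raises(ValueError):
            anm.anm_covariance(chain3, n_modes=50)


class TestPrs:
    def test_normalized_diagonal_is_one(self, toy_anm):
        pmap = anm.prs_scan(toy_anm)
        np.testing.assert_array_equal(np.diag(pmap.normalized), 1.0)
        assert np.all(pmap.raw_response >= 0)

    def test_decoupled_covariance_gives_no_cross_response(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        model = anm.build_anm(coords, cutoff=6.0)
        cov = np.kron(np.eye(2), np.diag([1.0, 2.0, 3.0]))
        blocks = cov.reshape(2, 3, 2, 3).transpose(0, 2, 1, 3)
        raw = np.einsum("ijab,ijab->ij", blocks, blocks).T / 3.0
        assert raw[0, 1] == 0.0 and raw[1, 0] == 0.0

    def test_sampled_directions_match_analytic_average(self, chain3):
        analytic = anm.prs_scan(chain3, n_modes=None)
        sampled = anm.prs_scan(
            chain3, n_modes=None, n_force_directions=10000, seed=3
        )
        mask = analytic.raw_response > 0
        rel = np.abs(
            sampled.raw_response[mask] / analytic.raw_response[mask] - 1.0
        )
        assert rel.max() < 0.02

    def test_normalized_map_invariant_to_gamma(self, toy_model):
        a = anm.prs_scan(anm.build_anm(toy_model.coordinates, gamma=1.0))
        b = anm.prs_scan(anm.build_anm(toy_model.coordinates, gamma=10.0))
        np.testing.assert_allclose(a.normalized, b.normalized, atol=1e-9)
        np.testing.assert_allclose(
            b.raw_response, a.raw_response / 100.0, rtol=1e-9
        )

    def test_effector_sensor_of_symmetric_map_coincide(self):
        mat = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.6], [0.2, 0.6, 1.0]])
        eff, sen = anm.effector_sensor(mat)
        np.testing.assert_allclose(eff, sen)

    def test_dominant_row_is_top_effector(self):
        mat = np.eye(4)
        mat[2, [0, 1, 3]] = 0.9
        eff, _ = anm.effector_sensor(mat)
        assert eff.argmax() == 2

    def test_chain_profiles_match_hand_computation(self, chain3):
        pmap = anm.prs_scan(chain3, n_modes=None)
        cov = anm.anm_covariance(chain3, n_modes=None)
        N = 3
        raw = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                block = cov[3 * j : 3 * j + 3, 3 * i : 3 * i + 3]
                raw[i, j] = np.sum(block**2) / 3.0
        norm = raw / np.diag(raw)[:, None]
        eff = np.array(
            [norm[i, [j for j in range(N) if j != i]].mean() for i in range(N)]
        )
        sen = np.array(
            [norm[[i for i in range(N) if i != j], j].mean() for j in range(N)]
        )
        np.testing.assert_allclose(pmap.effector_profile, eff, atol=1e-12)
        np.testing.assert_allclose(pmap.sensor_profile, sen, atol=1e-12)


class TestAveragedPrs:
    def test_identical_frames_average_to_single_frame_map(self, toy_model):
        coords = toy_model.coordinates
        ens = io.Ensemble(np.stack([coords] * 6))
        avg = anm.averaged_prs(ens, n_representatives=4)
        single = anm.prs_scan(anm.build_anm(coords))
        np.testing.assert_allclose(avg.normalized, single.normalized,
                                   atol=1e-12)

    def test_single_representative_equals_first_frame(self, toy_model):
        coords = toy_model.coordinates
        ens = io.Ensemble(np.stack([coords, coords + 0.2]))
        avg = anm.averaged_prs(ens, n_representatives=1)
        single = anm.prs_scan(anm.build_anm(coords))
        np.testing.assert_allclose(avg.normalized, single.normalized,
                                   atol=1e-12)

    def test_two_frame_mean_is_elementwise(self, toy_model):
        c0 = toy_model.coordinates
        c1 = c0 * 1.02
        ens = io.Ensemble(np.stack([c0, c1]))
        avg = anm.averaged_prs(ens, n_representatives=2)
        m0 = anm.prs_scan(anm.build_anm(c0)).normalized
        m1 = anm.prs_scan(anm.build_anm(c1)).normalized
        np.testing.assert_allclose(avg.normalized, (m0 + m1) / 2.0, atol=1e-12)

    def test_disconnected_frames_are_skipped_with_warning(self, toy_model):
        good = toy_model.coordinates
        bad = good.copy()
        bad[-1] += 100.0  # detach one node far beyond the cutoff
        ens = io.Ensemble(np.stack([good, bad]))
        with pytest.warns(UserWarning, match="skipped"):
            avg = anm.averaged_prs(ens, n_representatives=2)
        single = anm.prs_scan(anm.build_anm(good))
        np.testing.assert_allclose(avg.normalized, single.normalized,
                                   atol=1e-12)

    def test_all_frames_disconnected_is_an_error(self, toy_model):
        bad = toy_model.coordinates.copy()
        bad[-1] += 100.0
        ens = io.Ensemble(np.stack([bad, bad]))
        with pytest.warns(UserWarning):
            with pytest.raises(DisconnectedNetworkError):
                anm.averaged_prs(ens, n_representatives=2)
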