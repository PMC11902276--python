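import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ensdyn import io, metrics, synth
from oracles import grid_search_rmsd, quaternion_superpose


def _random_points(rng, n=8, scale=5.0):
    return rng.normal(scale=scale, size=(n, 3))


class TestSuperpose:
    def test_identity(self, rng):
        pts = _random_points(rng)
        R, t, rmsd = metrics.superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance(self, rng):
        pts = _random_points(rng)
        _, _, rmsd = metrics.superpose(pts + np.array([5.0, 0, 0]), pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self, rng):
        a = _random_points(rng)
        b = _random_points(rng)
        R, _, _ = metrics.superpose(a, b)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        ref = _random_points(rng, n=4)
        rot = Rotation.from_rotvec([0.4, -0.9, 0.2]).as_matrix()
        mobile = ref @ rot.T + rng.normal(scale=0.3, size=(4, 3))
        _, _, rmsd = metrics.superpose(mobile, ref)
        assert rmsd == pytest.approx(grid_search_rmsd(mobile, ref), abs=1e-6)

    def test_symmetry_after_fitting(self, rng):
        a = _random_points(rng)
        b = _random_points(rng)
        _, _, ab = metrics.superpose(a, b)
        _, _, ba = metrics.superpose(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(metrics.DegenerateGeometryError):
            metrics.superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_identical_frames_give_zero(self, toy_model, toy_nodes):
        coords = toy_model.coordinates
        ens = io.Ensemble(np.stack([coords] * 3), selection=toy_nodes)
        np.testing.assert_allclose(
            metrics.rmsd_series(ens, coords), 0.0, atol=1e-9
        )

    def test_rigid_rotation_is_removed(self, toy_model, rng):
        coords = toy_model.coordinates
        frames = []
        for _ in range(5):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            frames.append(coords @ R.T + rng.normal(size=3))
        ens = io.Ensemble(np.stack(frames))
        np.testing.assert_allclose(
            metrics.rmsd_series(ens, coords), 0.0, atol=1e-8
        )

    def test_matches_quaternion_kabsch_oracle(self, anm_ensemble):
        ens, _ = anm_ensemble
        sub = io.Ensemble(ens.coords[:40], selection=ens.selection)
        ref = ens.coords[0]
        series = metrics.rmsd_series(sub, ref)
        oracle = np.array(
            [quaternion_superpose(frame, ref) for frame in sub.coords]
        )
        np.testing.assert_allclose(series, oracle, atol=1e-6)


class TestRmsf:
    def test_constant_ensemble_is_zero(self, toy_model):
        ens = io.Ensemble(np.stack([toy_model.coordinates] * 4))
        np.testing.assert_allclose(metrics.rmsf(ens), 0.0, atol=1e-12)

    def test_symmetric_two_point_case(self):
        frames = np.zeros((10, 1, 3))
        frames[::2, 0, 0] = 1.5
        frames[1::2, 0, 0] = -1.5
        ens = io.Ensemble(frames)
        assert metrics.rmsf(ens, fit=False)[0] == pytest.approx(1.5)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_transform_of_all_frames(
        self, toy_model, toy_nodes, seed
    ):
        ens, _ = synth.sample_anm_ensemble(
            toy_model, n_frames=20, temperature_scale=0.3, seed=11,
            selection=toy_nodes,
        )
        rng = np.random.default_rng(seed)
        moved = np.empty_like(ens.coords)
        for f in range(ens.n_frames):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            moved[f] = ens.coords[f] @ R.T + rng.normal(scale=4.0, size=3)
        np.testing.assert_allclose(
            metrics.rmsf(io.Ensemble(moved)),
            metrics.rmsf(ens),
            atol=1e-6,
        )


class TestRgAndCom:
    def test_single_node_rg_is_zero(self):
        assert metrics.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert metrics.radius_of_gyration(frame) == pytest.approx(1.0)

    def test_rg_matches_direct_formula(self, rng):
        frame = _random_points(rng, n=20)
        masses = rng.uniform(1.0, 16.0, size=20)
        com = (masses[:, None] * frame).sum(0) / masses.sum()
        direct = np.sqrt(
            (masses * np.sum((frame - com) ** 2, axis=1)).sum() / masses.sum()
        )
        assert metrics.radius_of_gyration(frame, masses) == pytest.approx(
            direct, abs=1e-9
        )

    def test_com_constant_separation(self):
        frame = np.zeros((4, 3))
        frame[2:, 0] = 10.0
        ens = io.Ensemble(np.stack([frame] * 3))
        np.testing.assert_allclose(
            metrics.com_distance_series(ens, [0, 1], [2, 3]), 10.0
        )

    def test_com_three_four_five(self):
        a = np.zeros((2, 3))
        b = a + np.array([3.0, 4.0, 0.0])
        ens = io.Ensemble(np.concatenate([a, b])[None])
        assert metrics.com_distance_series(ens, [0, 1], [2, 3])[0] == (
            pytest.approx(5.0)
        )

    def test_com_matches_frame_loop(self, anm_ensemble):
        ens, _ = anm_ensemble
        sub = io.Ensemble(ens.coords[:25])
        a = list(range(0, 10))
        b = list(range(10, 24))
        series = metrics.com_distance_series(sub, a, b)
        for f in range(sub.n_frames):
            d = np.linalg.norm(
                sub.coords[f, a].mean(0) - sub.coords[f, b].mean(0)
            )
            assert series[f] == pytest.approx(d, abs=1e-12)

    def test_overlapping_groups_rejected(self, anm_ensemble):
        ens, _ = anm_ensemble
        with pytest.raises(ValueError):
            metrics.com_distance_series(ens, [0, 1], [1, 2])


class TestHBond:
    def _geometry(self, distance, angle_deg):
        donor = np.zeros(3)
        acceptor = np.array([distance, 0.0, 0.0])
        a = np.radians(angle_deg)
        hydrogen = np.array([np.cos(a), np.sin(a), 0.0])
        return donor, acceptor, hydrogen

    @pytest.mark.parametrize(
        "distance,angle,expected",
        [
            (3.0, 10.0, True),
            (3.6, 10.0, False),
            (3.5, 30.0, True),   # both boundaries inclusive
            (3.0, 45.0, False),  # angle beyond the cutoff
        ],
    )
    def test_criterion(self, distance, angle, expected):
        donor, acceptor, hydrogen = self._geometry(distance, angle)
        assert metrics.detect_hbond(donor, acceptor, hydrogen) is expected

    def test_distance_only_without_hydrogen(self):
        donor, acceptor, _ = self._geometry(3.2, 0.0)
        assert metrics.detect_hbond(donor, acceptor) is True
        donor, acceptor, _ = self._geometry(3.6, 0.0)
        assert metrics.detect_hbond(donor, acceptor) is False

    def test_occupancy_all_true(self):
        ev = synth.make_event_series(20, 1.0)
        report = metrics.hbond_occupancy(ev.donor, ev.acceptor, ev.hydrogen)
        assert report.occupancy == 1.0


def _bridge_frame(distance):
    return io.StructureModel(
        atoms=[
            io.Atom(1, "NH1", "ARG", 83, "A", np.zeros(3), "N"),
            io.Atom(2, "NH2", "ARG", 83, "A", np.array([-1.0, 1.0, 0.0]), "N"),
            io.Atom(3, "NE", "ARG", 83, "A", np.array([-1.0, -0.5, 0.0]), "N"),
            io.Atom(4, "OE1", "GLU", 86, "A",
                    np.array([distance, 0.0, 0.0]), "O"),
            io.Atom(5, "OE2", "GLU", 86, "A",
                    np.array([distance + 1.0, 0.0, 0.0]), "O"),
        ]
    )


class TestSaltBridges:
    def test_pair_within_cutoff_is_bridged(self):
        bridges = metrics.detect_salt_bridges(_bridge_frame(3.5))
        assert len(bridges) == 1
        assert bridges[0].label == "R83-E86"
        assert bridges[0].min_distance == pytest.approx(3.5)

    def test_pair_beyond_cutoff_is_not(self):
        assert metrics.detect_salt_bridges(_bridge_frame(4.5)) == []

    def test_occupancy_table_renders_percent(self):
        frames = [_bridge_frame(3.0)] * 73 + [_bridge_frame(6.0)] * 27
        table = metrics.salt_bridge_occupancy(frames)
        assert table.shape[0] == 1
        row = table.iloc[0]
        assert row["occupancy_percent"] == pytest.approx(73.0)
        assert row["formatted"] == "R83-E86 (73.0)"

    def test_percent_formatting_keeps_table_style(self):
        assert metrics.format_percent(73.04) == "73.04"
        assert metrics.format_percent(73.0) == "73.0"
        assert metrics.format_percent(1.2) == "1.2"


def test_mean_sd_string_convention():
    values = np.array([1.0, 2.0, 3.0])
    assert metrics.mean_sd_string(values) == "2.00 (0.82)"
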