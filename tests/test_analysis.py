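"""RMSD/RoG metrics, pair chronology, pathway classification, ensembles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from wallfold import analysis as an
from wallfold.analysis import (
    PairEvent,
    classify_pathway,
    detect_hbonds_atomistic,
    detect_pairs,
    ensemble_stats,
    folding_time,
    formation_order,
    kabsch_rmsd,
    landscape,
    pathway_report,
    rog,
    tf_align,
)
from wallfold.dynamics import Trajectory
from wallfold.io_cli import script_trajectory


def brute_force_min_rmsd(a, b, rng, n_grid=4000):
    """Independent oracle: random-rotation search + simplex refinement."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def rmsd_of(rot):
        d = rot.apply(ac) - bc
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    rots = Rotation.random(n_grid, random_state=rng)
    vals = [rmsd_of(r) for r in rots]
    best = rots[int(np.argmin(vals))]
    res = minimize(
        lambda rv: rmsd_of(Rotation.from_rotvec(rv)),
        best.as_rotvec(),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    return res.fun


def scan_first_window(flags, w):
    """Oracle: first start index of w consecutive True values."""
    for s in range(len(flags) - w + 1):
        if all(flags[s : s + w]):
            return s
    return None


def _traj(positions, times, metadata=None):
    return Trajectory(
        np.asarray(positions, float), np.asarray(times, float), None, metadata or {}
    )


class TestKabschRMSD:
    def test_zero_against_itself(self, native, system):
        assert kabsch_rmsd(native, native, system.stem_bead_indices) < 1e-12

    def test_invariant_under_rigid_motion(self, native, rng):
        x = native.coordinates
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = x @ rot.T + rng.uniform(-30, 30, 3)
        assert kabsch_rmsd(x, moved) < 1e-8

    def test_symmetric(self, native, rng):
        a = native.coordinates
        b = a + 0.8 * rng.standard_normal(a.shape)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)

    def test_superposed_not_larger_than_raw(self, native, rng):
        a = native.coordinates
        for _ in range(5):
            b = a + rng.standard_normal(a.shape)
            rot = Rotation.random(random_state=rng).as_matrix()
            b = b @ rot.T + rng.uniform(-5, 5, 3)
            assert kabsch_rmsd(a, b) <= kabsch_rmsd(a, b, superpose=False) + 1e-12

    def test_matches_rotation_search_oracle(self, rng):
        # includes the minimal-asymmetry case: two points on the x-axis
        # augmented to 3, against a scaled copy
        base = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.3, 0.9, 0.1]])
        cases = [
            (base, 1.7 * base),
            (rng.standard_normal((6, 3)), rng.standard_normal((6, 3))),
            (rng.standard_normal((10, 3)), rng.standard_normal((10, 3))),
        ]
        for a, b in cases:
            assert kabsch_rmsd(a, b) == pytest.approx(
                brute_force_min_rmsd(a, b, rng), abs=1e-3
            )

    def test_collinear_subset_flagged(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            kabsch_rmsd(line, line + 1.0)

    def test_too_small_subset_rejected(self):
        two = np.zeros((2, 3))
        with pytest.raises(ValueError):
            kabsch_rmsd(two, two)


class TestRog:
    def test_single_point_is_zero(self):
        assert rog(np.zeros((1, 3))) == 0.0

    def test_unit_square_corners(self):
        sq = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float
        )
        assert rog(sq) == pytest.approx(np.sqrt(0.5))

    def test_matches_direct_formula_on_random_cloud(self, rng):
        x = rng.standard_normal((36, 3)) * 7
        mean = x.mean(axis=0)
        direct = np.sqrt(
            np.mean(
                (x[:, 0] - mean[0]) ** 2
                + (x[:, 1] - mean[1]) ** 2
                + (x[:, 2] - mean[2]) ** 2
            )
        )
        assert rog(x) == pytest.approx(direct, abs=1e-14)

    def test_rigid_motion_invariant(self, rng):
        x = rng.standard_normal((20, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        assert rog(x @ rot.T + 11.0) == pytest.approx(rog(x), abs=1e-10)

    def test_mass_weighted_variant(self, rng):
        x = rng.standard_normal((5, 3))
        m = rng.uniform(1, 10, 5)
        com = (m[:, None] * x).sum(0) / m.sum()
        expected = np.sqrt((m * ((x - com) ** 2).sum(1)).sum() / m.sum())
        assert rog(x, masses=m) == pytest.approx(expected, abs=1e-12)


class TestHbondDetection:
    def _triple(self, d, angle_deg):
        donor = np.array([0.0, 0.0, 0.0])
        acceptor = np.array([d, 0.0, 0.0])
        cosang = np.cos(np.radians(angle_deg))
        y = np.sqrt((d * d / 4.0) * (1.0 + cosang) / (1.0 - cosang))
        hydrogen = np.array([d / 2.0, y, 0.0])
        return np.stack([donor, hydrogen, acceptor])

    @pytest.mark.parametrize(
        "d, angle, bonded",
        [(3.4, 150.0, True), (3.6, 180.0, False), (3.0, 119.0, False),
         (3.49, 121.0, True)],
    )
    def test_distance_and_angle_criterion(self, d, angle, bonded):
        x = self._triple(d, angle)
        bonds = detect_hbonds_atomistic(x, [0], [1], [2])
        assert ((0, 1, 2) in bonds) is bonded

    def test_missing_hydrogen_rejected(self):
        x = self._triple(3.2, 160.0)
        with pytest.raises(ValueError):
            detect_hbonds_atomistic(x, [0], [None], [2])


class TestDetectPairs:
    def test_native_frame_all_formed(self, system, native):
        assert detect_pairs(native, system) == set(system.pairs)

    def test_extended_frame_none_formed(self, system, extended):
        assert detect_pairs(extended, system) == set()

    def test_enlarging_cutoff_never_removes_pairs(self, system, native, rng):
        x = native.coordinates + 1.5 * rng.standard_normal((36, 3))
        previous = set()
        for cf in (0.8, 1.0, 1.2, 1.5, 2.0):
            formed = detect_pairs(x, system, cutoff_factor=cf)
            assert previous <= formed
            previous = formed

    def test_atomistic_requires_all_native_bonds(self, system):
        hbond_map = {
            (4, 9): [(0, 1, 2), (3, 4, 5), (6, 7, 8)],
            (1, 12): [(9, 10, 11), (12, 13, 14)],
        }
        present = {(0, 1, 2), (3, 4, 5), (9, 10, 11), (12, 13, 14)}
        formed = detect_pairs(
            None, system, mode="atomistic", hbond_map=hbond_map, present_bonds=present
        )
        assert formed == {(1, 12)}  # (4,9) is missing one of its three bonds

    def test_unknown_mode_rejected(self, system, native):
        with pytest.raises(ValueError):
            detect_pairs(native, system, mode="quantum")


class TestFormationOrder:
    def test_scripted_order_recovered(self, system):
        tr = script_trajectory(system, [(2, 11), (4, 9), (3, 10), (1, 12)])
        order = [e.pair for e in formation_order(tr, system)]
        assert order == [(2, 11), (4, 9), (3, 10), (1, 12)]

    def test_flicker_shorter_than_window_is_ignored(self, system):
        hold = 7
        tr = script_trajectory(
            system, [(4, 9), (3, 10), (2, 11), (1, 12)],
            hold_frames=hold, flicker=3,
        )
        events = formation_order(tr, system, persistence_frames=5)
        t49 = next(e for e in events if e.pair == (4, 9)).formation_time_ns
        # the three single-frame blinks (frames hold..hold+5) are ignored;
        # formation is dated to the first frame of the persistent stage
        first_persistent_frame = hold + 2 * 3
        assert t49 == pytest.approx(tr.times_ns[first_persistent_frame])

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(1, 6))
    def test_first_persistent_matches_window_scan_oracle(self, flags, w):
        assert an._first_persistent(np.array(flags), w) == scan_first_window(flags, w)

    def test_simultaneous_formation_tie_broken_and_flagged(self, system, native):
        # two frames of extended then native held: all pairs form at the
        # same frame
        from wallfold.rna_model import build_extended_chain

        ext = build_extended_chain(system).coordinates
        frames = [ext, ext] + [native.coordinates] * 6
        tr = _traj(frames, np.arange(8) * 0.02)
        events = formation_order(tr, system, persistence_frames=5)
        assert [e.pair for e in events] == [(1, 12), (2, 11), (3, 10), (4, 9)]
        assert all(e.tied for e in events)


class TestFoldingTime:
    def test_never_folding_returns_none(self, system):
        tr = script_trajectory(
            system, [(4, 9), (3, 10), (2, 11), (1, 12)], fold=False
        )
        assert folding_time(tr, system) is None

    def test_native_from_frame_zero(self, system, native):
        tr = _traj([native.coordinates] * 8, np.arange(8) * 0.02)
        assert folding_time(tr, system) == 0.0

    def test_crossing_frame_matches_brute_scan(self, system, native, extended):
        frames = [extended.coordinates] * 4 + [native.coordinates] * 7
        tr = _traj(frames, np.arange(11) * 0.5)
        t = folding_time(tr, system, persistence_frames=5)
        rmsds = [
            kabsch_rmsd(f, native, system.stem_bead_indices) for f in frames
        ]
        k = scan_first_window([r < 2.0 for r in rmsds], 5)
        assert t == pytest.approx(tr.times_ns[k])
        assert t == pytest.approx(2.0)

    def test_no_fit_variant_uses_raw_formula(self, system, native, rng):
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = native.coordinates @ rot.T + 40.0
        tr = _traj([moved] * 6, np.arange(6) * 0.02)
        assert folding_time(tr, system) == 0.0  # superposed: still native
        assert folding_time(tr, system, superpose=False) is None


class TestClassifyPathway:
    def test_loop_adjacent_first_is_path_i(self):
        order = [PairEvent(p, t) for t, p in
                 [(1.0, (4, 9)), (2.0, (3, 10)), (3.0, (2, 11)), (4.0, (1, 12))]]
        call = classify_pathway("t", True, 5.0, order)
        assert call.label == an.PATH_I

    def test_distal_first_is_path_ii(self):
        order = [PairEvent(p, t) for t, p in
                 [(1.0, (2, 11)), (2.0, (3, 10)), (3.0, (1, 12)), (4.0, (4, 9))]]
        call = classify_pathway("t", True, 5.0, order)
        assert call.label == an.PATH_II

    def test_unfolded_is_unclassified(self):
        order = [PairEvent((4, 9), 1.0)]
        call = classify_pathway("t", False, None, order)
        assert call.label == an.UNCLASSIFIED

    def test_folded_without_loop_adjacent_pair_is_unclassified(self):
        order = [PairEvent((2, 11), 1.0), PairEvent((3, 10), 2.0)]
        call = classify_pathway("t", True, 5.0, order)
        assert call.label == an.UNCLASSIFIED

    def test_folded_trajectories_partition_into_exactly_one_path(self, system):
        for scripted_order in (
            [(4, 9), (3, 10), (2, 11), (1, 12)],
            [(1, 12), (2, 11), (3, 10), (4, 9)],
            [(3, 10), (4, 9), (2, 11), (1, 12)],
        ):
            tr = script_trajectory(system, scripted_order)
            call = an.analyze_trajectory(tr, system)
            assert call.folded
            assert (call.label == an.PATH_I) != (call.label == an.PATH_II)


class TestTfAlign:
    def test_ctf_subtracts_transcription_duration(self):
        tr = _traj(np.zeros((1, 3, 3)), [110.0],
                   {"mode": "ctf", "dt_ns": 10.0, "n_residues": 12})
        assert tf_align(tr)[0] == pytest.approx(0.0)

    def test_ff_time_unchanged(self):
        tr = _traj(np.zeros((1, 3, 3)), [37.0], {"mode": "ff"})
        assert tf_align(tr)[0] == pytest.approx(37.0)

    def test_frames_during_transcription_are_negative(self):
        tr = _traj(np.zeros((1, 3, 3)), [500.0],
                   {"mode": "ctf", "dt_ns": 100.0, "n_residues": 12})
        assert tf_align(tr)[0] == pytest.approx(-600.0)

    def test_missing_metadata_rejected(self):
        with pytest.raises(KeyError):
            tf_align(_traj(np.zeros((1, 3, 3)), [0.0], {}))
        with pytest.raises(KeyError):
            tf_align(_traj(np.zeros((1, 3, 3)), [0.0], {"mode": "ctf"}))


class TestEnsembleStats:
    def test_single_trajectory_flagged(self, system, native):
        tr = _traj([native.coordinates] * 3, [0.0, 1.0, 2.0], {"mode": "ff"})
        table = ensemble_stats([tr], [1.0], system)
        row = table.iloc[0]
        assert row["n"] == 1
        assert row["rmsd_sd"] == 0.0
        assert bool(row["single_sample"])

    def test_identical_trajectories_have_zero_sd(self, system, native):
        tr = lambda: _traj([native.coordinates] * 3, [0.0, 1.0, 2.0], {"mode": "ff"})
        table = ensemble_stats([tr(), tr()], [2.0], system)
        assert table.iloc[0]["rog_sd"] == 0.0
        assert table.iloc[0]["n"] == 2

    def test_matches_hand_computed_mean_sd(self, system, native, extended):
        confs = [native.coordinates, extended.coordinates, native.coordinates]
        trajs = [
            _traj([c] * 2, [0.0, 1.0], {"mode": "ff"}) for c in confs
        ]
        table = ensemble_stats(trajs, [1.0], system)
        rogs = [rog(c) for c in confs]
        rmsds = [
            kabsch_rmsd(c, native, system.stem_bead_indices) for c in confs
        ]
        row = table.iloc[0]
        assert row["rog_mean"] == pytest.approx(np.mean(rogs))
        assert row["rog_sd"] == pytest.approx(np.std(rogs, ddof=1))
        assert row["rmsd_mean"] == pytest.approx(np.mean(rmsds))
        assert row["n"] == 3

    def test_no_frame_near_target_rejected(self, system, native):
        tr = _traj([native.coordinates] * 2, [0.0, 1.0], {"mode": "ff"})
        with pytest.raises(ValueError):
            ensemble_stats([tr], [10.0], system)


class TestLandscape:
    def test_single_frame_single_bin(self, system, native):
        tr = _traj([native.coordinates], [0.0], {"mode": "ff"})
        ls = landscape([tr], system, bins=5)
        assert ls.counts.sum() == pytest.approx(1.0)
        assert (ls.counts > 0).sum() == 1

    def test_folded_only_with_no_folded_rejected(self, system):
        tr = script_trajectory(
            system, [(4, 9), (3, 10), (2, 11), (1, 12)], fold=False
        )
        with pytest.raises(ValueError):
            landscape([tr], system, folded_only=True)

    def test_normalization(self, system, native, extended, rng):
        frames = [
            native.coordinates + 0.3 * rng.standard_normal((36, 3))
            for _ in range(17)
        ]
        tr = _traj(frames, np.arange(17) * 0.02, {"mode": "ff"})
        ls = landscape([tr], system, bins=6)
        assert abs(ls.counts.sum() - 1.0) < 1e-12


class TestPathwayReport:
    def _call(self, label, condition="ff"):
        return classify_pathway(
            "x",
            label != an.UNCLASSIFIED,
            1.0 if label != an.UNCLASSIFIED else None,
            [PairEvent((4, 9), 0.5)] if label == an.PATH_I
            else [PairEvent((2, 11), 0.5), PairEvent((4, 9), 1.0)]
            if label == an.PATH_II
            else [],
            condition=condition,
        )

    def test_four_one_zero_row(self):
        calls = [self._call(an.PATH_I)] * 4 + [self._call(an.PATH_II)]
        table = pathway_report(calls)
        row = table.iloc[0]
        assert (row["path_i"], row["path_ii"], row["unclassified"]) == (4, 1, 0)
        assert row["path_ii_fraction"] == pytest.approx(0.2)

    def test_empty_input_gives_zero_row(self):
        table = pathway_report([])
        assert table.iloc[0][["path_i", "path_ii", "unclassified", "n"]].tolist() == [
            0, 0, 0, 0,
        ]

    def test_counts_sum_to_number_of_calls(self):
        calls = (
            [self._call(an.PATH_I)] * 3
            + [self._call(an.PATH_II)] * 2
            + [self._call(an.UNCLASSIFIED)] * 4
        )
        row = pathway_report(calls).iloc[0]
        assert row["path_i"] + row["path_ii"] + row["unclassified"] == row["n"] == 9


class TestFullPipelineOnStaticNative:
    def test_native_held_static_reports_immediate_fold(self, system, native):
        tr = _traj(
            [native.coordinates] * 10,
            np.arange(10) * 0.02,
            {"mode": "ff", "seed": 0},
        )
        call = an.analyze_trajectory(tr, system, trajectory_id="static")
        assert call.folded
        assert call.folding_time_ns == 0.0
        assert {e.pair for e in call.formation_order} == set(system.pairs)
        assert kabsch_rmsd(tr.positions[0], native, system.stem_bead_indices) < 1e-12
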