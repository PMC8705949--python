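"""Geometric stability metrics: examples, oracles and invariances."""

import numpy as np
import pytest

from conftest import (
    brute_contact_map,
    brute_hbonds,
    brute_salt_bridges,
    make_beta_ladder,
    random_toy_structure,
    rigid_transform,
)
from synucleo import synthetic_data as sd
from synucleo.fibril_metrics import (
    HydrogensRequiredError,
    SaltBridgeCriterion,
    assign_secondary_structure,
    average_ss_fractions,
    compute_subunit_distances,
    contact_map,
    count_salt_bridges,
    detect_hbonds,
    inter_subunit_hbonds,
    list_salt_bridges,
)
from synucleo.structio import Atom, Structure, Trajectory


def _atoms(spec):
    """spec: list of (name, element, resname, resindex, chain, xyz)."""
    return Structure(
        [Atom(i + 1, n, e, rn, ri, c, np.array(p, float))
         for i, (n, e, rn, ri, c, p) in enumerate(spec)]
    )


class TestSubunitDistances:
    def test_three_four_five(self):
        st = _atoms([
            ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
            ("CA", "C", "ALA", 1, "B", (3, 4, 0)),
        ])
        traj = Trajectory(st, [st.positions])
        (series,) = compute_subunit_distances(traj, [("A", "B")], atom_scope="all")
        assert series.values[0] == pytest.approx(5.0)

    def test_rigid_translate_forces_com_offset(self, fibril):
        st, truth = fibril
        traj = Trajectory(st, [st.positions])
        series = compute_subunit_distances(traj, atom_scope="all")
        for s in series:
            assert s.values[0] == pytest.approx(truth.adjacent_com_distance, abs=1e-9)

    def test_dissociation_series_monotone(self, dissociation_traj):
        series = compute_subunit_distances(dissociation_traj)
        s12 = series[0].values
        assert np.all(np.diff(s12) > 0)
        for s in series[1:]:
            assert np.ptp(s.values) < 1e-6

    def test_unknown_chain_is_usage_error(self, fibril):
        st, _ = fibril
        traj = Trajectory(st, [st.positions])
        with pytest.raises(ValueError, match="unknown chain"):
            compute_subunit_distances(traj, [("A", "Z")])


class TestContactMap:
    def _two_res(self, d):
        return _atoms([
            ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
            ("CA", "C", "ALA", 2, "A", (d, 0, 0)),
        ])

    def test_below_cutoff_contact(self):
        cm = contact_map(self._two_res(6.4))
        assert cm.contacts[0, 1]

    def test_exactly_at_cutoff_is_not_contact(self):
        """'below 6.5 Å' is strict: a pair at exactly 6.5 Å is no contact."""
        cm = contact_map(self._two_res(6.5))
        assert not cm.contacts[0, 1]

    def test_diagonal_false_and_symmetric(self, fibril):
        st, _ = fibril
        cm = contact_map(st)
        assert not np.diag(cm.contacts).any()
        assert np.array_equal(cm.contacts, cm.contacts.T)

    def test_sequence_separation_excludes_neighbours(self):
        st = _atoms([
            ("CA", "C", "ALA", 1, "A", (0, 0, 0)),
            ("CA", "C", "ALA", 2, "A", (3, 0, 0)),
            ("CA", "C", "ALA", 3, "A", (6, 0, 0)),
        ])
        cm = contact_map(st, min_sequence_separation=2)
        assert not cm.contacts[0, 1] and not cm.contacts[1, 2]
        assert cm.contacts[0, 2]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce(self, seed):
        st = random_toy_structure(seed)
        cm = contact_map(st)
        oracle = brute_contact_map(st)
        for i, ki in enumerate(cm.residue_labels):
            for j, kj in enumerate(cm.residue_labels):
                assert cm.contacts[i, j] == oracle[(ki, kj)], (ki, kj)


class TestHBonds:
    def test_collinear_bond(self):
        st = _atoms([
            ("N", "N", "ALA", 1, "A", (0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (1, 0, 0)),
            ("O", "O", "ALA", 2, "B", (3.2, 0, 0)),
        ])
        (hb,) = detect_hbonds(st)
        assert hb.distance_xy == pytest.approx(3.2)
        assert hb.angle_xhy == pytest.approx(180.0)
        assert not hb.is_intra_subunit

    def test_distance_fails(self):
        st = _atoms([
            ("N", "N", "ALA", 1, "A", (0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (1, 0, 0)),
            ("O", "O", "ALA", 2, "A", (3.6, 0, 0)),
        ])
        assert detect_hbonds(st) == []

    def test_right_angle_fails(self):
        st = _atoms([
            ("N", "N", "ALA", 1, "A", (0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (1, 0, 0)),
            ("O", "O", "ALA", 2, "A", (1, 2.5, 0)),
        ])
        assert detect_hbonds(st) == []

    def test_no_hydrogens_is_explicit_error(self):
        st = _atoms([("N", "N", "ALA", 1, "A", (0, 0, 0))])
        with pytest.raises(HydrogensRequiredError, match="hydrogens required"):
            detect_hbonds(st)

    @pytest.mark.parametrize("seed", range(100, 125))
    def test_matches_bruteforce(self, seed):
        st = random_toy_structure(seed)
        try:
            got = {
                (b.donor_atom.serial, b.hydrogen_atom.serial, b.acceptor_atom.serial)
                for b in detect_hbonds(st)
            }
        except HydrogensRequiredError:
            got = None
        if got is not None:
            assert got == brute_hbonds(st)

    def test_fibril_ground_truth(self, fibril):
        st, truth = fibril
        bonds = detect_hbonds(st)
        intra = sum(b.is_intra_subunit for b in bonds)
        assert intra == truth.n_intra_hbonds
        assert len(bonds) - intra == truth.n_inter_hbonds


class TestInterSubunitArithmetic:
    @pytest.mark.parametrize("total,intra,expected", [(10, 7, 3), (5, 5, 0), (0, 0, 0)])
    def test_subtraction(self, total, intra, expected):
        assert inter_subunit_hbonds(total, intra) == expected

    def test_invariant_violation(self):
        with pytest.raises(ValueError):
            inter_subunit_hbonds(3, 4)

    def test_two_counting_routes_agree(self, fibril):
        """total − intra equals the direct count of inter-chain records."""
        st, _ = fibril
        bonds = detect_hbonds(st)
        intra = sum(b.is_intra_subunit for b in bonds)
        direct = sum(not b.is_intra_subunit for b in bonds)
        assert inter_subunit_hbonds(len(bonds), intra) == direct


class TestSaltBridges:
    def _pair(self, d, chain_b="B"):
        return _atoms([
            ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
            ("CD", "C", "GLU", 2, chain_b, (d, 0, 0)),
        ])

    @pytest.mark.parametrize("d,expected", [(4.4, 1), (4.5, 1), (4.6, 0)])
    def test_threshold_inclusive(self, d, expected):
        # r_ij = |r_i − r_j| − d0 ≤ 0 counts, so 4.5 Å itself is a bridge
        assert count_salt_bridges(self._pair(d)) == expected

    def test_scope_filtering(self):
        st = _atoms([
            ("NZ", "N", "LYS", 1, "A", (0, 0, 0)),
            ("CD", "C", "GLU", 2, "A", (4.0, 0, 0)),
            ("NZ", "N", "LYS", 3, "B", (0, 10, 0)),
            ("CD", "C", "GLU", 4, "B", (4.0, 10, 0)),
        ])
        assert count_salt_bridges(st, scope="intra") == 2
        assert count_salt_bridges(st, scope="inter") == 0
        assert count_salt_bridges(st, scope="all") == 2

    def test_fibril_ground_truth(self, fibril):
        st, truth = fibril
        assert count_salt_bridges(st, scope="inter") == truth.n_inter_salt_bridges
        assert count_salt_bridges(st, scope="intra") == truth.n_intra_salt_bridges
        for _, _, d in list_salt_bridges(st):
            assert d == pytest.approx(truth.salt_bridge_distance, abs=0.05)

    @pytest.mark.parametrize("seed", range(200, 225))
    @pytest.mark.parametrize("scope", ["all", "intra", "inter"])
    def test_matches_bruteforce(self, seed, scope):
        st = random_toy_structure(seed)
        assert count_salt_bridges(st, scope=scope) == brute_salt_bridges(st, scope=scope)

    def test_bad_d0(self):
        with pytest.raises(ValueError):
            SaltBridgeCriterion(d0=-1.0)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", range(300, 310))
    def test_counts_invariant(self, seed):
        st = random_toy_structure(seed)
        moved = rigid_transform(st, seed + 1)
        cm0, cm1 = contact_map(st), contact_map(moved)
        assert np.array_equal(cm0.contacts, cm1.contacts)
        assert count_salt_bridges(st) == count_salt_bridges(moved)
        try:
            n0 = len(detect_hbonds(st))
        except HydrogensRequiredError:
            n0 = None
        if n0 is not None:
            assert len(detect_hbonds(moved)) == n0

    def test_distances_invariant(self, fibril):
        st, _ = fibril
        moved = rigid_transform(st, 7)
        t0 = Trajectory(st, [st.positions])
        t1 = Trajectory(st, [moved.positions])
        for s0, s1 in zip(compute_subunit_distances(t0), compute_subunit_distances(t1)):
            assert s1.values[0] == pytest.approx(s0.values[0], abs=1e-6)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        st = sd.make_ideal_backbone(-57.0, -47.0, 20)
        labels = assign_secondary_structure(st)
        assert all(l == "H" for l in labels[2:-2])

    def test_beta_ladder_is_e(self):
        labels = assign_secondary_structure(make_beta_ladder(6))
        assert labels == ["E"] * 12

    def test_lone_extended_chain_is_coil(self):
        st = sd.make_ideal_backbone(-180.0, 180.0, 12)
        assert assign_secondary_structure(st) == ["C"] * 12

    def test_missing_backbone_atom_warns_coil(self):
        st = _atoms([
            ("N", "N", "ALA", 1, "A", (0, 0, 0)),
            ("CA", "C", "ALA", 1, "A", (1.5, 0, 0)),
        ])
        with pytest.warns(UserWarning, match="missing backbone"):
            assert assign_secondary_structure(st) == ["C"]


class TestAverageSSFractions:
    def _mixed_traj(self):
        helix = sd.make_ideal_backbone(-57.0, -47.0, 20)
        coil = sd.make_ideal_backbone(-180.0, 180.0, 20)
        return Trajectory(helix, [helix.positions, helix.positions, coil.positions])

    def test_two_thirds_one_third(self):
        traj = self._mixed_traj()
        ss = average_ss_fractions(traj)
        interior = slice(2, -2)
        np.testing.assert_allclose(ss.averaged_fractions[interior, 0], 2 / 3)
        np.testing.assert_allclose(ss.averaged_fractions[interior, 2], 1 / 3)

    def test_fractions_sum_to_one(self):
        ss = average_ss_fractions(self._mixed_traj())
        np.testing.assert_allclose(ss.averaged_fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_single_frame_window_is_indicator(self):
        traj = self._mixed_traj()
        ss = average_ss_fractions(traj, window=(2, 3))
        assert set(np.unique(ss.averaged_fractions)) <= {0.0, 1.0}

    def test_whole_window_equals_explicit_loop(self):
        traj = self._mixed_traj()
        ss = average_ss_fractions(traj)
        acc = np.zeros_like(ss.averaged_fractions)
        for k in range(traj.n_frames):
            labels = assign_secondary_structure(traj.frame_structure(k))
            for r, lab in enumerate(labels):
                acc[r, {"H": 0, "E": 1, "C": 2}[lab]] += 1
        np.testing.assert_allclose(ss.averaged_fractions, acc / traj.n_frames)

    def test_time_window_selection(self):
        traj = self._mixed_traj()
        traj.frame_times = np.array([100.0, 300.0, 450.0])
        ss = average_ss_fractions(traj, time_window=(200.0, 500.0))
        assert ss.per_frame_labels.shape[0] == 2

    def test_empty_window_is_usage_error(self):
        with pytest.raises(ValueError, match="empty"):
            average_ss_fractions(self._mixed_traj(), window=(3, 3))
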