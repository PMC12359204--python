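import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lanthimodel.restraints import (
    AtomGroup,
    NOERestraint,
    RestraintError,
    effective_distance,
    ensemble_average_distance,
    parse_restraints_tsv,
    parse_upl,
    resolve_group,
    restraint_distance_matrix,
    score_ensemble,
    write_restraints_tsv,
)
from lanthimodel.geometry import Conformer
from lanthimodel.topology import parse_topology


def point_conformer(points):
    """One CA per residue at the given coordinates — a minimal geometry."""
    topo = parse_topology("seq " + "A" * len(points) + "\n")
    atoms = tuple((i + 1, "CA", "C") for i in range(len(points)))
    return Conformer(topo, atoms, np.asarray(points, float))


def ca_group(pos):
    return AtomGroup(((pos, "CA"),))


class TestEffectiveDistance:
    def test_single_pair_is_euclidean(self):
        c = point_conformer([[0, 0, 0], [2, 0, 0]])
        assert effective_distance(c, ca_group(1), ca_group(2)) == \
            pytest.approx(2.0)

    def test_two_atom_group_value(self):
        # frozen from the direct formula: (2^-6 + 4^-6)^(-1/6) = 1.99483...
        c = point_conformer([[0, 0, 0], [2, 0, 0], [-4, 0, 0]])
        g_pair = AtomGroup(((2, "CA"), (3, "CA")))
        expected = (2.0 ** -6 + 4.0 ** -6) ** (-1 / 6)
        d = effective_distance(c, ca_group(1), g_pair)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(1.9948, abs=1e-3)

    def test_homogeneous_degree_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 3)) * 3
        c1 = point_conformer(pts)
        c2 = point_conformer(2 * pts)
        g_a = AtomGroup(((1, "CA"), (2, "CA")))
        g_b = AtomGroup(((3, "CA"), (4, "CA")))
        assert effective_distance(c2, g_a, g_b) == pytest.approx(
            2 * effective_distance(c1, g_a, g_b), rel=1e-12)

    def test_unresolvable_atom_named(self):
        c = point_conformer([[0, 0, 0], [2, 0, 0]])
        with pytest.raises(Exception, match="HB"):
            effective_distance(c, ca_group(1), AtomGroup(((2, "HB"),)))


class TestEnsembleAverage:
    def restraint(self):
        return NOERestraint(ca_group(1), ca_group(2), d_obs=3.0)

    def members_at(self, distances):
        return [point_conformer([[0, 0, 0], [d, 0, 0]]) for d in distances]

    def test_single_member_identity(self):
        (m,) = self.members_at([2.5])
        assert ensemble_average_distance([m], self.restraint()) == \
            pytest.approx(2.5)

    def test_equal_distances_identity(self):
        ms = self.members_at([3.0, 3.0, 3.0])
        assert ensemble_average_distance(ms, self.restraint()) == \
            pytest.approx(3.0)

    def test_two_state_value(self):
        # frozen from the direct formula: ((2^-6 + 4^-6)/2)^(-1/6) = 2.2394
        ms = self.members_at([2.0, 4.0])
        d = ensemble_average_distance(ms, self.restraint())
        assert d == pytest.approx(((2.0 ** -6 + 4.0 ** -6) / 2) ** (-1 / 6),
                                  abs=1e-12)
        assert d == pytest.approx(2.2394, abs=1e-3)

    def test_empty_ensemble_errors(self):
        with pytest.raises(RestraintError, match="empty"):
            ensemble_average_distance([], self.restraint())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1.0, 10.0), min_size=1, max_size=8))
    def test_power_mean_bounds(self, distances):
        """min d_i <= d* <= max d_i for every member set."""
        ms = self.members_at(distances)
        d_star = ensemble_average_distance(ms, self.restraint())
        assert min(distances) - 1e-9 <= d_star <= max(distances) + 1e-9

    def test_adding_shorter_member_decreases_dstar(self):
        ms = self.members_at([3.0, 4.0, 5.0])
        base = ensemble_average_distance(ms, self.restraint())
        closer = ensemble_average_distance(
            ms + self.members_at([2.0]), self.restraint())
        assert closer < base

    def test_permutation_invariant(self):
        ms = self.members_at([2.0, 3.5, 5.0])
        r = self.restraint()
        assert ensemble_average_distance(ms, r) == pytest.approx(
            ensemble_average_distance(ms[::-1], r), abs=1e-12)


class TestScoring:
    def test_perfect_ensemble_scores_zero(self):
        ms = [point_conformer([[0, 0, 0], [3.0, 0, 0]])]
        r = NOERestraint(ca_group(1), ca_group(2), d_obs=3.0, kind="target")
        assert score_ensemble(ms, [r]).total == pytest.approx(0.0, abs=1e-18)

    def test_half_angstrom_residual(self):
        ms = [point_conformer([[0, 0, 0], [3.5, 0, 0]])]
        r = NOERestraint(ca_group(1), ca_group(2), d_obs=3.0, kind="target")
        assert score_ensemble(ms, [r]).total == pytest.approx(0.25)

    def test_upper_limit_one_sided(self):
        ms = [point_conformer([[0, 0, 0], [2.0, 0, 0]])]
        r = NOERestraint(ca_group(1), ca_group(2), d_obs=3.0,
                         kind="upper_limit")
        assert score_ensemble(ms, [r]).total == pytest.approx(0.0)
        assert score_ensemble(ms, [r], mode="symmetric").total == \
            pytest.approx(1.0)

    def test_matches_brute_force_recomputation(self, pool8):
        topo = pool8[0].topology
        rs = parse_restraints_tsv(
            "3 H 7 H 4.0 target\n2 HA 8 H 5.0 upper_limit\n", topo)
        sub = pool8[:3]
        score = score_ensemble(sub, rs)
        total = 0.0
        for r in rs:
            inv6 = [effective_distance(m, r.group_a, r.group_b) ** -6
                    for m in sub]
            d_star = (np.mean(inv6)) ** (-1 / 6)
            res = d_star - r.d_obs
            if r.kind == "upper_limit":
                res = max(0.0, res)
            total += res ** 2
        assert score.total == pytest.approx(total, rel=1e-12)


class TestParsers:
    def test_tsv_with_pseudoatoms(self, topo15):
        rs = parse_restraints_tsv(
            "# comment\n3 HN 10 H 4.0\n5 HA 13 MB 5.0 target\n", topo15)
        assert len(rs) == 2
        assert rs[0].kind == "upper_limit"
        assert rs[0].group_a.members == ((3, "H"),)     # HN normalized
        assert rs[1].group_b.members == ((13, "CB"),)   # Ala methyl
        assert rs[1].group_b.label == "MB"

    def test_gly_qa_expands_to_two_protons(self, topo15):
        g = resolve_group(topo15, 3, "QA")
        assert set(g.members) == {(3, "HA2"), (3, "HA3")}

    def test_upl_dialect(self, topo15):
        rs = parse_upl("3 GLY H 10 GLY H 4.50\n", topo15)
        assert len(rs) == 1
        assert rs[0].kind == "upper_limit"
        assert rs[0].d_obs == pytest.approx(4.5)

    def test_round_trip_through_writer(self, topo15):
        rs = parse_restraints_tsv("3 H 10 H 4.0 target\n", topo15)
        again = parse_restraints_tsv(write_restraints_tsv(rs), topo15)
        assert again == rs

    def test_malformed_line_numbered(self, topo15):
        with pytest.raises(RestraintError, match="line 2"):
            parse_restraints_tsv("3 H 10 H 4.0\n3 H 10\n", topo15)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(RestraintError, match="disjoint"):
            NOERestraint(ca_group(1), ca_group(1), d_obs=3.0)

    def test_distance_matrix_shape(self, pool8):
        topo = pool8[0].topology
        rs = parse_restraints_tsv("3 H 7 H 4.0\n", topo)
        m = restraint_distance_matrix(pool8[:4], rs)
        assert m.shape == (4, 1)
        assert m[0, 0] == pytest.approx(
            effective_distance(pool8[0], rs[0].group_a, rs[0].group_b))
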