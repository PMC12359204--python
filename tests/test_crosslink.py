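import numpy as np
import pytest

from lanthimodel.crosslink import (
    CrosslinkGeometry,
    build_ideal_ring_fragment,
    close_ring,
    measure_crosslink,
)
from lanthimodel.geometry import GeometryError, build_conformer, measure_phi_psi
from lanthimodel.topology import parse_topology


@pytest.fixture(scope="module")
def closed8(topo8_module):
    conf = build_conformer(
        topo8_module, np.random.default_rng(1).uniform(-180, 180, (8, 2)))
    result = close_ring(conf, topo8_module.rings[0])
    assert result.converged
    return result.conformer


@pytest.fixture(scope="module")
def topo8_module():
    return parse_topology("seq AAAAACAA\nring 2-6 lan\n")


class TestMeasure:
    def test_ideal_fragment_zero_penalty(self):
        frag = build_ideal_ring_fragment()
        report = measure_crosslink(frag, frag.topology.rings[0])
        assert report.total == pytest.approx(0.0, abs=1e-18)
        assert all(t.deviation == pytest.approx(0, abs=1e-9)
                   for t in report.terms)

    def test_stretched_bond_deviation(self):
        frag = build_ideal_ring_fragment()
        stretched = frag.copy()
        i_cb = frag.index_of(1, "CB")
        i_sg = frag.index_of(2, "SG")
        direction = frag.coords[i_sg] - frag.coords[i_cb]
        direction /= np.linalg.norm(direction)
        stretched.coords[i_sg] += 0.5 * direction
        report = measure_crosslink(stretched, frag.topology.rings[0])
        assert report.term("cs_bond").deviation == pytest.approx(0.5, abs=1e-9)

    def test_total_is_sum_of_terms(self, closed8, topo8_module):
        report = measure_crosslink(closed8, topo8_module.rings[0])
        assert report.total == pytest.approx(
            sum(t.weight * t.deviation ** 2 for t in report.terms))
        assert all(t.deviation >= 0 for t in report.terms)

    def test_random_ring_matches_independent_recomputation(
            self, closed8, topo8_module):
        """Brute-force re-measurement with raw vector math."""
        from lanthimodel.geometry import bond_angle, dihedral
        g = CrosslinkGeometry()
        ring = topo8_module.rings[0]
        cb_d = closed8.xyz(2, "CB")
        sg = closed8.xyz(6, "SG")
        ca_d = closed8.xyz(2, "CA")
        cb_a = closed8.xyz(6, "CB")
        report = measure_crosslink(closed8, ring, g)
        assert report.term("cs_bond").observed == pytest.approx(
            float(np.linalg.norm(cb_d - sg)))
        assert report.term("angle_ca_cb_sg").observed == pytest.approx(
            bond_angle(ca_d, cb_d, sg))
        assert report.term("angle_cb_sg_cb").observed == pytest.approx(
            bond_angle(cb_d, sg, cb_a))

    def test_missing_atom_named(self, topo8_module):
        conf = build_conformer(topo8_module, np.zeros((8, 2)))
        stripped_atoms = tuple(a for a in conf.atoms if a[1] != "SG")
        keep = [i for i, a in enumerate(conf.atoms) if a[1] != "SG"]
        from lanthimodel.geometry import Conformer
        c2 = Conformer(topo8_module, stripped_atoms, conf.coords[keep])
        with pytest.raises(GeometryError, match="SG"):
            measure_crosslink(c2, topo8_module.rings[0])

    def test_methyllanthionine_extra_terms(self):
        topo = parse_topology("seq A[ABU]AAAC\nring 2-6 melan\n")
        conf = build_conformer(
            topo, np.random.default_rng(0).uniform(-180, 180, (6, 2)))
        report = measure_crosslink(conf, topo.rings[0])
        names = {t.name for t in report.terms}
        assert {"improper_methyl", "angle_ca_cb_cg", "angle_cg_cb_sg"} <= names


class TestCloseRing:
    def test_converges_from_random_starts(self, topo8_module):
        ok = 0
        for seed in range(10):
            conf = build_conformer(
                topo8_module,
                np.random.default_rng(seed).uniform(-180, 180, (8, 2)))
            result = close_ring(conf, topo8_module.rings[0])
            ok += result.converged
        assert ok >= 9

    def test_near_closed_reconverges(self, closed8, topo8_module):
        rng = np.random.default_rng(5)
        pert = closed8.copy()
        for kind, res in [("psi", 2), ("phi", 3), ("psi", 3), ("phi", 4),
                          ("psi", 4), ("phi", 5), ("psi", 5), ("phi", 6)]:
            pert.rotate_torsion(kind, res, rng.normal(0, 10))
        result = close_ring(pert, topo8_module.rings[0])
        assert result.converged
        assert result.gap < 0.02

    def test_already_closed_is_fixed_point(self, closed8, topo8_module):
        result = close_ring(closed8, topo8_module.rings[0])
        assert result.converged
        assert np.abs(result.conformer.coords - closed8.coords).max() < 1e-9

    def test_outside_span_torsions_untouched(self, topo8_module):
        conf = build_conformer(
            topo8_module,
            np.random.default_rng(2).uniform(-180, 180, (8, 2)))
        before = measure_phi_psi(conf)
        result = close_ring(conf, topo8_module.rings[0])
        after = measure_phi_psi(result.conformer)
        outside = [0, 6, 7]  # residues 1, 7, 8 (0-based rows)
        assert np.allclose(before[outside], after[outside],
                           atol=1e-9, equal_nan=True)

    def test_preserves_bonds_and_angles(self, topo8_module):
        """Closure moves torsions only: every bond length and angle of the
        backbone is identical before and after."""
        from lanthimodel.geometry import bond_angle
        conf = build_conformer(
            topo8_module,
            np.random.default_rng(3).uniform(-180, 180, (8, 2)))
        result = close_ring(conf, topo8_module.rings[0])
        closed = result.conformer
        bb = conf.select(("N", "CA", "C"))
        for i in range(len(bb) - 1):
            d0 = np.linalg.norm(conf.coords[bb[i + 1]] - conf.coords[bb[i]])
            d1 = np.linalg.norm(
                closed.coords[bb[i + 1]] - closed.coords[bb[i]])
            assert d1 == pytest.approx(d0, abs=1e-9)
        for i in range(len(bb) - 2):
            a0 = bond_angle(conf.coords[bb[i]], conf.coords[bb[i + 1]],
                            conf.coords[bb[i + 2]])
            a1 = bond_angle(closed.coords[bb[i]], closed.coords[bb[i + 1]],
                            closed.coords[bb[i + 2]])
            assert a1 == pytest.approx(a0, abs=1e-7)

    def test_no_rotatable_torsions_errors(self):
        topo = parse_topology("seq ACA\nring 1-2 lan\n")
        conf = build_conformer(topo, np.zeros((3, 2)))
        with pytest.raises(GeometryError, match="rotatable"):
            close_ring(conf, topo.rings[0])

    def test_failure_reports_gap(self, topo8_module):
        conf = build_conformer(
            topo8_module,
            np.random.default_rng(4).uniform(-180, 180, (8, 2)))
        result = close_ring(conf, topo8_module.rings[0], max_iter=1)
        assert result.gap >= 0.0
        assert isinstance(result.converged, bool)
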