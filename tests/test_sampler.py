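import numpy as np
import pytest

from lanthimodel.crosslink import CrosslinkGeometry
from lanthimodel.geometry import backbone_rmsd, build_conformer, measure_phi_psi
from lanthimodel.sampler import (
    SamplerConfig,
    SamplerError,
    SimpleScore,
    refine,
    sample_and_refine,
    sample_from_start,
    sample_unstructured,
)
from lanthimodel.topology import parse_topology


class TestSimpleScore:
    def test_clash_free_conformer_has_zero_clash(self, topo8):
        conf = build_conformer(topo8, np.tile([-120.0, 130.0], (8, 1)))
        assert SimpleScore().clash(conf) == pytest.approx(0.0)

    def test_compact_random_chain_can_clash(self, topo8):
        rng = np.random.default_rng(0)
        clashes = [SimpleScore().clash(
            build_conformer(topo8, rng.uniform(-40, 0, (8, 2))))
            for _ in range(5)]
        assert max(clashes) > 0

    def test_helix_has_backbone_hbonds(self):
        topo = parse_topology("seq " + "A" * 12 + "\n")
        conf = build_conformer(topo, np.tile([-57.0, -47.0], (12, 1)))
        assert SimpleScore().hbond_count(conf) >= 4

    def test_score_decreases_with_crosslink_deviation(self, pool8, topo8):
        score = SimpleScore()
        good = pool8[0]
        bad = good.copy()
        bad.rotate_torsion("phi", 4, 60.0)  # strains the 2-6 ring
        assert score.crosslink(bad) > score.crosslink(good)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SimpleScore(clash_weight=-1.0)


class TestSampleUnstructured:
    def test_pool_closed_and_sorted(self, pool8, topo8, simple_score):
        geometry = CrosslinkGeometry()
        for conf in pool8:
            cb = conf.xyz(2, "CB")
            sg = conf.xyz(6, "SG")
            gap = abs(np.linalg.norm(cb - sg) - geometry.cs_bond_length)
            assert gap < 0.02 + 1e-9
        scores = [simple_score(c) for c in pool8]
        assert scores == sorted(scores)

    def test_ring_free_topology_skips_closure(self):
        topo = parse_topology("seq AAAAA\n")
        pool = sample_unstructured(topo, SamplerConfig(n_models=5, seed=0))
        assert len(pool) == 5

    def test_same_seed_identical_pool(self, topo8):
        cfg = SamplerConfig(n_models=4, seed=123)
        p1 = sample_unstructured(topo8, cfg)
        p2 = sample_unstructured(topo8, cfg)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.coords, b.coords)

    def test_torsions_drawn_from_tables(self, pool8, topo8):
        """No sampled conformer sits in a masked Ramachandran cell."""
        from lanthimodel.torsions import table_for_residue
        ring_span = set(range(2, 7))
        for conf in pool8:
            pp = measure_phi_psi(conf)
            for r in range(2, len(topo8) + 1):
                if r in ring_span:  # closure rewrites these torsions
                    continue
                spec = topo8.residue(r)
                t = table_for_residue(spec.code, spec.chirality)
                i, j = t.cell_index(pp[r - 1, 0], pp[r - 1, 1])
                assert not t.mask[i, j]


class TestRefine:
    def test_zero_magnitude_at_minimum_is_identity(self, pool8):
        score = SimpleScore()
        cfg = SamplerConfig(burn_in=0, production=20, small_move_deg=0.0,
                            shear_move_deg=0.0, seed=0)
        out = refine(pool8[0], score, cfg)
        assert np.allclose(out.coords, pool8[0].coords)

    def test_output_never_worse_than_input(self, pool8):
        score = SimpleScore()
        cfg = SamplerConfig(burn_in=10, production=40, seed=1)
        for conf in pool8[:3]:
            out = refine(conf, score, cfg)
            assert score(out) <= score(conf) + 1e-9

    def test_clashing_start_improves(self):
        # ring-free chain: refinement is free to resolve clashes without
        # the thioether-gap guard vetoing moves
        topo = parse_topology("seq AAAAAAAA\n")
        score = SimpleScore()
        improved = 0
        tried = 0
        for seed in range(20):
            conf = build_conformer(
                topo, np.random.default_rng(seed).uniform(-40, 0, (8, 2)))
            if score.clash(conf) == 0:
                continue
            tried += 1
            cfg = SamplerConfig(burn_in=5, production=60, seed=seed,
                                small_move_deg=6.0)
            out = refine(conf, score, cfg)
            improved += score.clash(out) < score.clash(conf)
        assert tried > 0
        assert improved / tried >= 0.8


class TestSampleFromStart:
    def test_zero_steps_gives_copies(self, pool8, topo8):
        cfg = SamplerConfig(n_models=3, burn_in=0, production=0, seed=0)
        pool = sample_from_start(pool8[0], topo8, cfg)
        assert len(pool) == 3
        for conf in pool:
            assert np.allclose(conf.coords, pool8[0].coords)

    def test_topology_mismatch_errors(self, pool8):
        other = parse_topology("seq AAA\n")
        with pytest.raises(SamplerError, match="match"):
            sample_from_start(pool8[0], other, SamplerConfig(n_models=1))

    def test_flexible_linker_has_highest_variance(self):
        """A helix with a glycine linker: perturbation concentrates there."""
        topo = parse_topology("seq AAAAGGGAAAA\n")
        pp = np.tile([-57.0, -47.0], (11, 1))
        start = build_conformer(topo, pp)
        # glycine's broad map lets moves through; alanine's alpha basin
        # penalizes departures, so torsion variance peaks at the linker
        cfg = SamplerConfig(n_models=8, burn_in=0, production=150,
                            large_move_deg=20.0, mc_temperature=0.3, seed=5)
        pool = sample_from_start(start, topo, cfg)
        pps = np.stack([measure_phi_psi(c) for c in pool])
        from lanthimodel.analysis import circular_variance
        var = np.array([circular_variance(pps[:, r, 1])
                        for r in range(11)])
        linker = var[4:7].mean()
        helix = np.concatenate([var[1:4], var[7:10]]).mean()
        assert linker > helix

    def test_seed_determinism(self, pool8, topo8):
        cfg = SamplerConfig(n_models=2, burn_in=5, production=20, seed=9)
        p1 = sample_from_start(pool8[0], topo8, cfg)
        p2 = sample_from_start(pool8[0], topo8, cfg)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.coords, b.coords)


class TestTwoStage:
    def test_stagewise_mean_score_improves(self, topo8):
        cfg = SamplerConfig(n_models=12, burn_in=5, production=40,
                            top_fraction=0.25, seed=4)
        pool, means = sample_and_refine(topo8, cfg)
        initial, top, refined = means
        assert top <= initial
        assert refined <= top + 1e-9
        assert len(pool) == 3
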