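import numpy as np
import pytest

from lanthimodel.restraints import parse_restraints_tsv
from lanthimodel.selection import (
    EnsembleNOEModel,
    SelectionError,
    SelectorConfig,
    ShiftTable,
    exhaustive_from_distances,
    metropolis_accept,
    select_by_filter,
    select_from_distances,
)


def planted_instance(rng, n_pool=12, n_rest=15, k_true=3):
    """Distances matrix plus observations generated from a planted subset."""
    d = rng.uniform(2.0, 8.0, (n_pool, n_rest))
    idx = rng.choice(n_pool, k_true, replace=False)
    d_obs = (np.mean(d[idx] ** -6.0, axis=0)) ** (-1 / 6)
    return d, d_obs, ["target"] * n_rest, idx


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"size_min": 5, "size_init": 3, "size_max": 10},
        {"steps": 0},
        {"temperature": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SelectionError):
            SelectorConfig(**kwargs)


class TestMetropolis:
    def test_improvements_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-0.5, 1.0, rng) for _ in range(100))

    def test_worsening_frequency_matches_boltzmann(self):
        """Empirical acceptance of a fixed worsening move is exp(-d/T)."""
        rng = np.random.default_rng(1)
        delta, temp, n = 1.0, 1.0, 10_000
        accepted = sum(metropolis_accept(delta, temp, rng)
                       for _ in range(n))
        p = np.exp(-delta / temp)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 2.576 * sigma  # 99% binomial bound


class TestSelectFromDistances:
    def test_recovers_planted_subset(self):
        rng = np.random.default_rng(5)
        d, d_obs, kinds, idx = planted_instance(rng)
        cfg = SelectorConfig(steps=20_000, size_min=2, size_max=4,
                             size_init=3, temperature=0.05, seed=0)
        state, _ = select_from_distances(d, d_obs, kinds, cfg)
        assert state.score == pytest.approx(0.0, abs=1e-12)
        assert set(state.indices) == set(idx)

    def test_matches_exhaustive_on_small_instances(self):
        matches = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            d, d_obs, kinds, _ = planted_instance(rng)
            cfg = SelectorConfig(steps=20_000, size_min=2, size_max=4,
                                 size_init=3, temperature=0.05, seed=seed)
            state, _ = select_from_distances(d, d_obs, kinds, cfg)
            oracle = exhaustive_from_distances(d, d_obs, kinds, 2, 4)
            matches += state.score <= oracle.score + 1e-9
        assert matches >= 9

    def test_same_seed_same_result(self):
        rng = np.random.default_rng(2)
        d, d_obs, kinds, _ = planted_instance(rng)
        cfg = SelectorConfig(steps=5_000, size_min=2, size_max=5,
                             size_init=3, seed=42)
        s1, t1 = select_from_distances(d, d_obs, kinds, cfg, trace_every=100)
        s2, t2 = select_from_distances(d, d_obs, kinds, cfg, trace_every=100)
        assert s1 == s2
        assert t1 == t2

    def test_size_bounds_respected(self):
        rng = np.random.default_rng(3)
        d, d_obs, kinds, _ = planted_instance(rng, n_pool=15)
        cfg = SelectorConfig(steps=5_000, size_min=3, size_max=6,
                             size_init=4, seed=1)
        state, _ = select_from_distances(d, d_obs, kinds, cfg)
        assert 3 <= state.size <= 6

    def test_pool_too_small_errors(self):
        d = np.full((3, 2), 3.0)
        cfg = SelectorConfig(steps=10, size_min=5, size_init=5, size_max=6)
        with pytest.raises(SelectionError, match="too small"):
            select_from_distances(d, [3.0, 3.0], ["target"] * 2, cfg)


class TestExhaustive:
    def test_single_member_bound(self):
        d = np.array([[3.4], [4.0], [2.9]])
        state = exhaustive_from_distances(d, [3.0], ["target"], 1, 1)
        assert state.indices == (2,)  # closest to the observation

    def test_empty_restraint_effect(self):
        # with a trivially satisfied observation every minimal subset wins
        d = np.full((4, 1), 3.0)
        state = exhaustive_from_distances(d, [3.0], ["target"], 1, 2)
        assert state.score == pytest.approx(0.0, abs=1e-18)
        assert state.size == 1

    def test_combinatorial_bound_enforced(self):
        d = np.full((60, 1), 3.0)
        with pytest.raises(SelectionError, match="exceed"):
            exhaustive_from_distances(d, [3.0], ["target"], 1, 60)


class TestSelectByFilter:
    def test_two_stage_membership(self):
        """250 models with crafted metrics: stage one keeps the 200 best by
        NOE agreement, stage two the 20 lowest energies of those."""
        rng = np.random.default_rng(7)
        noe = rng.permutation(250).astype(float)
        energy = rng.permutation(250).astype(float)
        picked = select_by_filter(noe, energy, 200, 20)
        stage1 = set(np.argsort(noe, kind="stable")[:200])
        assert set(picked) <= stage1
        best_energy = sorted(stage1, key=lambda i: energy[i])[:20]
        assert set(picked) == set(best_energy)

    def test_coinciding_rankings(self):
        noe = np.arange(50.0)
        energy = np.arange(50.0)
        assert set(select_by_filter(noe, energy, 30, 10)) == set(range(10))

    def test_n_final_exceeding_n_restraint_errors(self):
        with pytest.raises(SelectionError, match="exceed"):
            select_by_filter(np.zeros(30), np.zeros(30), 10, 20)

    def test_small_pool_errors(self):
        with pytest.raises(SelectionError, match="smaller"):
            select_by_filter(np.zeros(5), np.zeros(5), 200, 20)


class TestModelResults:
    def make_model(self, pool8):
        topo = pool8[0].topology
        rs = parse_restraints_tsv(
            "3 H 7 H 4.0 target\n2 HA 8 H 5.0 target\n"
            "4 H 8 HA 4.5 target\n", topo)
        return EnsembleNOEModel(pool8, rs)

    def test_fit_summary_reports_selection(self, pool8):
        model = self.make_model(pool8)
        cfg = SelectorConfig(steps=2_000, size_min=2, size_max=4,
                             size_init=2, seed=0)
        res = model.fit(cfg)
        text = res.summary()
        assert "ensemble size" in text
        assert f"{len(pool8)}" in text
        table = res.restraint_table()
        assert len(table) == 3
        assert (table["d_star"] > 0).all()

    def test_exhaustive_method_matches_mc(self, pool8):
        model = self.make_model(pool8)
        cfg = SelectorConfig(steps=20_000, size_min=2, size_max=3,
                             size_init=2, temperature=0.05, seed=3)
        mc = model.fit(cfg, method="mc")
        ex = model.fit(cfg, method="exhaustive")
        assert mc.score == pytest.approx(ex.score, abs=1e-9)

    def test_filter_method_requires_energies(self, pool8):
        model = self.make_model(pool8)
        with pytest.raises(SelectionError, match="energies"):
            model.fit(method="filter")

    def test_filter_method_runs(self, pool8):
        model = self.make_model(pool8)
        energies = np.arange(len(pool8), dtype=float)
        cfg = SelectorConfig(steps=10, size_min=2, size_max=6, size_init=4)
        res = model.fit(cfg, method="filter", energies=energies)
        assert res.state.size == 4
        assert set(res.state.indices) <= set(range(len(pool8)))


class TestShiftTable:
    def test_mask_requires_canonical_neighborhood(self, topo15):
        # topo15 has DHA at 14: positions 13-15 are untrusted
        columns = [(p, "CA") for p in range(1, 16)]
        table = ShiftTable.from_values(
            np.zeros((3, 15)), np.zeros(15), columns, topo15)
        masked_in = {p for (p, _n), ok in zip(columns, table.mask) if ok}
        assert 13 not in masked_in
        assert 14 not in masked_in
        assert 15 not in masked_in
        assert 1 not in masked_in  # no left neighbor
        assert 5 in masked_in

    def test_shift_term_steers_selection(self):
        """Two pool members with identical distances: shifts decide."""
        d = np.full((4, 2), 3.0)
        d_obs = [3.0, 3.0]
        kinds = ["target", "target"]
        pred = np.array([[0.0], [5.0], [5.0], [5.0]])
        obs = np.array([0.0])
        cfg = SelectorConfig(steps=3_000, size_min=1, size_max=1,
                             size_init=1, temperature=0.05, seed=0)
        state, _ = select_from_distances(
            d, d_obs, kinds, cfg, shift_pred=pred, shift_obs=obs)
        assert state.indices == (0,)
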