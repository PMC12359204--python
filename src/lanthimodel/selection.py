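"""Ensemble selection against ensemble-averaged NOE restraints.

The selection problem: given a pool of candidate conformers and a set of
NOE observations, find the subset (the *ensemble*) whose r^-6-averaged
distances best reproduce the observations.  The search is a Metropolis
Monte Carlo over ensemble membership with three moves — add a member,
remove a member, swap a member with a non-member — constrained to a size
window, scored by the sum of squared restraint residuals, and returning
the lowest-scoring state visited.

Because the per-conformer effective distances never change during the
search, they are computed once into a pool-by-restraint matrix and the
r^-6 sums are updated incrementally per move.

``EnsembleNOEModel`` wraps the search in a model/results interface:
``EnsembleNOEModel(pool, restraints).fit()`` returns an
``EnsembleFitResults`` with the selected members, per-restraint residuals
and a ``summary()`` table.  ``exhaustive_select`` enumerates every allowed
subset and serves as the small-instance oracle.  ``select_by_filter``
implements the alternative two-stage path: keep the structures that best
match the NOEs individually, then rank those by conformational energy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, exp

import numpy as np
import pandas as pd

from .restraints import restraint_distance_matrix
from .topology import LanthipeptideTopology

__all__ = [
    "SelectorConfig",
    "EnsembleState",
    "ShiftTable",
    "SelectionError",
    "metropolis_accept",
    "select_from_distances",
    "select_ensemble",
    "exhaustive_from_distances",
    "exhaustive_select",
    "select_by_filter",
    "EnsembleNOEModel",
    "EnsembleFitResults",
]


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectorConfig:
    """Knobs of the membership Monte Carlo.

    Defaults mirror the published protocol: 500,000 steps, ensemble size
    held between 10 and 30 starting from 20.  The acceptance temperature
    is in score units (squared Angstroms); the protocol does not pin it,
    so it is an explicit parameter here.
    """

    steps: int = 500_000
    size_min: int = 10
    size_max: int = 30
    size_init: int = 20
    temperature: float = 1.0
    seed: int | None = None
    shift_weight: float = 1.0
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.size_min <= self.size_init <= self.size_max):
            raise SelectionError(
                "need 1 <= size_min <= size_init <= size_max"
            )
        if self.steps <= 0:
            raise SelectionError("steps must be positive")
        if self.temperature <= 0:
            raise SelectionError("temperature must be positive")


@dataclass(frozen=True)
class EnsembleState:
    """A selected ensemble: pool indices plus the cached restraint score."""

    indices: tuple[int, ...]
    score: float

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ShiftTable:
    """Predicted per-conformer chemical shifts vs observations.

    ``predicted`` is (n_pool, n_cols); column ``k`` belongs to
    ``columns[k] = (residue position, nucleus)``.  ``mask`` marks columns
    trusted for scoring — only positions whose residue and both sequence
    neighbors are canonical, where empirical shift predictors are
    reliable.  Ensemble shifts average linearly (arithmetic mean over
    members), unlike NOE distances.
    """

    predicted: np.ndarray
    observed: np.ndarray
    columns: tuple[tuple[int, str], ...]
    mask: np.ndarray

    @classmethod
    def from_values(cls, predicted, observed, columns,
                    topology: LanthipeptideTopology) -> "ShiftTable":
        predicted = np.asarray(predicted, float)
        observed = np.asarray(observed, float)
        columns = tuple((int(p), str(nuc)) for p, nuc in columns)
        if predicted.ndim != 2 or predicted.shape[1] != len(columns):
            raise SelectionError("predicted shape mismatch with columns")
        if observed.shape != (len(columns),):
            raise SelectionError("observed shape mismatch with columns")
        n = len(topology)

        def canonical(pos: int) -> bool:
            return (1 <= pos <= n
                    and topology.residue(pos).code in _CANONICAL_CODES)

        mask = np.array([
            canonical(p) and canonical(p - 1) and canonical(p + 1)
            for p, _nuc in columns
        ])
        return cls(predicted, observed, columns, mask)


_CANONICAL_CODES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Boltzmann acceptance: always for improvements, with probability
    exp(-delta/T) for worsening moves."""
    if delta <= 0:
        return True
    return rng.random() < exp(-delta / temperature)


def _ensemble_score(s_inv6: np.ndarray, k: int, d_obs: np.ndarray,
                    one_sided: np.ndarray) -> float:
    d_star = (s_inv6 / k) ** (-1.0 / 6.0)
    res = d_star - d_obs
    res = np.where(one_sided, np.maximum(res, 0.0), res)
    return float(res @ res)


def select_from_distances(distances: np.ndarray, d_obs, kinds,
                          config: SelectorConfig,
                          rng: np.random.Generator | None = None,
                          mode: str = "kind_aware",
                          shift_pred: np.ndarray | None = None,
                          shift_obs: np.ndarray | None = None,
                          trace_every: int = 0):
    """Membership Monte Carlo on a precomputed distance matrix.

    ``distances[i, j]`` is the effective distance of restraint ``j`` in
    pool member ``i``.  Returns ``(EnsembleState, trace)`` where trace is
    a list of (step, current score, best score, size) samples when
    ``trace_every > 0``, else an empty list.
    """
    distances = np.asarray(distances, float)
    n_pool, n_rest = distances.shape
    d_obs = np.asarray(d_obs, float)
    one_sided = np.array(
        [mode != "symmetric" and k == "upper_limit" for k in kinds]
    )
    if d_obs.shape != (n_rest,) or one_sided.shape != (n_rest,):
        raise SelectionError("observations do not match distance matrix")
    if n_pool <= config.size_min:
        raise SelectionError(
            f"pool of {n_pool} too small for size_min {config.size_min}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    dinv6 = distances ** -6.0
    use_shifts = shift_pred is not None
    if use_shifts:
        shift_pred = np.asarray(shift_pred, float)
        shift_obs = np.asarray(shift_obs, float)

    members = list(rng.choice(n_pool, size=config.size_init,
                              replace=config.allow_duplicates))
    member_set = set(members)
    s = dinv6[members].sum(axis=0)
    sh = shift_pred[members].sum(axis=0) if use_shifts else None

    def current_score() -> float:
        k = len(members)
        total = _ensemble_score(s, k, d_obs, one_sided)
        if use_shifts:
            dev = sh / k - shift_obs
            total += config.shift_weight * float(dev @ dev)
        return total

    score = current_score()
    best_score = score
    best = tuple(sorted(members))
    trace: list[tuple[int, float, float, int]] = []

    for step in range(1, config.steps + 1):
        move = rng.integers(3)  # 0 add, 1 remove, 2 swap
        k = len(members)
        new_members = None
        if move == 0 and k < config.size_max:
            if config.allow_duplicates:
                cand = int(rng.integers(n_pool))
            else:
                outside = [i for i in range(n_pool) if i not in member_set]
                if not outside:
                    cand = None
                else:
                    cand = outside[int(rng.integers(len(outside)))]
            if cand is not None:
                new_members = members + [cand]
                s_new = s + dinv6[cand]
                sh_new = sh + shift_pred[cand] if use_shifts else None
        elif move == 1 and k > config.size_min:
            drop = int(rng.integers(k))
            cand = members[drop]
            new_members = members[:drop] + members[drop + 1:]
            s_new = s - dinv6[cand]
            sh_new = sh - shift_pred[cand] if use_shifts else None
        elif move == 2:
            drop = int(rng.integers(k))
            old = members[drop]
            if config.allow_duplicates:
                new = int(rng.integers(n_pool))
            else:
                outside = [i for i in range(n_pool) if i not in member_set]
                new = (outside[int(rng.integers(len(outside)))]
                       if outside else None)
            if new is not None:
                new_members = members[:drop] + [new] + members[drop + 1:]
                s_new = s - dinv6[old] + dinv6[new]
                sh_new = (sh - shift_pred[old] + shift_pred[new]
                          if use_shifts else None)
        # moves violating the size bounds (or with no eligible candidate)
        # are rejected as invalid proposals
        if new_members is not None:
            k_new = len(new_members)
            total = _ensemble_score(s_new, k_new, d_obs, one_sided)
            if use_shifts:
                dev = sh_new / k_new - shift_obs
                total += config.shift_weight * float(dev @ dev)
            if metropolis_accept(total - score, config.temperature, rng):
                members = new_members
                member_set = set(members)
                s = s_new
                if use_shifts:
                    sh = sh_new
                score = total
                if score < best_score:
                    best_score = score
                    best = tuple(sorted(members))
        if trace_every and step % trace_every == 0:
            trace.append((step, score, best_score, len(members)))

    return EnsembleState(best, best_score), trace


def select_ensemble(pool, restraints, config: SelectorConfig | None = None,
                    shifts: ShiftTable | None = None,
                    mode: str = "kind_aware") -> EnsembleState:
    """Run the membership Monte Carlo on a conformer pool."""
    config = config or SelectorConfig()
    restraints = list(restraints)
    distances = restraint_distance_matrix(pool, restraints)
    state, _ = select_from_distances(
        distances,
        [r.d_obs for r in restraints],
        [r.kind for r in restraints],
        config,
        mode=mode,
        shift_pred=(shifts.predicted[:, shifts.mask]
                    if shifts is not None else None),
        shift_obs=(shifts.observed[shifts.mask]
                   if shifts is not None else None),
    )
    return state


_MAX_EXHAUSTIVE = 1_000_000


def exhaustive_from_distances(distances: np.ndarray, d_obs, kinds,
                              size_min: int, size_max: int,
                              mode: str = "kind_aware") -> EnsembleState:
    distances = np.asarray(distances, float)
    n_pool = distances.shape[0]
    total_subsets = sum(comb(n_pool, k)
                        for k in range(size_min, size_max + 1))
    if total_subsets > _MAX_EXHAUSTIVE:
        raise SelectionError(
            f"{total_subsets} subsets exceed the exhaustive bound"
        )
    d_obs = np.asarray(d_obs, float)
    one_sided = np.array(
        [mode != "symmetric" and k == "upper_limit" for k in kinds]
    )
    dinv6 = distances ** -6.0
    best = None
    best_score = np.inf
    for k in range(size_min, size_max + 1):
        for subset in itertools.combinations(range(n_pool), k):
            s = dinv6[list(subset)].sum(axis=0)
            sc = _ensemble_score(s, k, d_obs, one_sided)
            if sc < best_score:
                best_score = sc
                best = subset
    if best is None:
        raise SelectionError("no admissible subset")
    return EnsembleState(tuple(best), best_score)


def exhaustive_select(pool, restraints, size_min: int, size_max: int,
                      mode: str = "kind_aware") -> EnsembleState:
    """Global optimum by enumeration — the small-instance oracle."""
    restraints = list(restraints)
    distances = restraint_distance_matrix(pool, restraints)
    return exhaustive_from_distances(
        distances, [r.d_obs for r in restraints],
        [r.kind for r in restraints], size_min, size_max, mode)


def select_by_filter(restraint_totals, energies,
                     n_restraint: int = 200, n_final: int = 20
                     ) -> tuple[int, ...]:
    """Two-stage filter: best ``n_restraint`` by NOE agreement, then best
    ``n_final`` of those by energy.  Ties keep input order (stable sort)."""
    restraint_totals = np.asarray(restraint_totals, float)
    energies = np.asarray(energies, float)
    n = restraint_totals.shape[0]
    if energies.shape != (n,):
        raise SelectionError("metric arrays differ in length")
    if n_final > n_restraint:
        raise SelectionError("n_final cannot exceed n_restraint")
    if n < n_final:
        raise SelectionError(f"pool of {n} smaller than n_final={n_final}")
    stage1 = np.argsort(restraint_totals, kind="stable")[:n_restraint]
    order2 = stage1[np.argsort(energies[stage1], kind="stable")]
    return tuple(int(i) for i in order2[:n_final])


# ---------------------------------------------------------------------------
# Model / Results


class EnsembleNOEModel:
    """NOE-restrained ensemble model over a fixed conformer pool.

    Parameters
    ----------
    pool : sequence of Conformer
        Candidate conformers sharing one topology.
    restraints : sequence of NOERestraint
    shifts : ShiftTable, optional
        Adds the mean-shift deviation term to the selection score.
    mode : {"kind_aware", "symmetric"}
        Residual convention for upper-limit restraints.
    """

    def __init__(self, pool, restraints, shifts: ShiftTable | None = None,
                 mode: str = "kind_aware"):
        self.pool = list(pool)
        self.restraints = list(restraints)
        if not self.pool:
            raise SelectionError("empty conformer pool")
        if not self.restraints:
            raise SelectionError("no restraints")
        self.shifts = shifts
        self.mode = mode
        self._distances: np.ndarray | None = None

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = restraint_distance_matrix(
                self.pool, self.restraints)
        return self._distances

    def per_model_totals(self) -> np.ndarray:
        """Single-conformer restraint score for every pool member."""
        d_obs = np.array([r.d_obs for r in self.restraints])
        one_sided = np.array([
            self.mode != "symmetric" and r.kind == "upper_limit"
            for r in self.restraints
        ])
        res = self.distances - d_obs
        res = np.where(one_sided, np.maximum(res, 0.0), res)
        return np.einsum("ij,ij->i", res, res)

    def fit(self, config: SelectorConfig | None = None,
            method: str = "mc", energies=None,
            trace_every: int = 0) -> "EnsembleFitResults":
        """Select the ensemble.

        ``method="mc"`` runs the membership Monte Carlo;
        ``method="filter"`` needs per-model ``energies`` and applies the
        two-stage NOE-then-energy filter;
        ``method="exhaustive"`` enumerates (small pools only).
        """
        config = config or SelectorConfig()
        d_obs = [r.d_obs for r in self.restraints]
        kinds = [r.kind for r in self.restraints]
        trace: list = []
        if method == "mc":
            state, trace = select_from_distances(
                self.distances, d_obs, kinds, config, mode=self.mode,
                shift_pred=(self.shifts.predicted[:, self.shifts.mask]
                            if self.shifts is not None else None),
                shift_obs=(self.shifts.observed[self.shifts.mask]
                           if self.shifts is not None else None),
                trace_every=trace_every,
            )
        elif method == "exhaustive":
            state = exhaustive_from_distances(
                self.distances, d_obs, kinds,
                config.size_min, config.size_max, self.mode)
        elif method == "filter":
            if energies is None:
                raise SelectionError(
                    "method='filter' needs per-model energies"
                )
            idx = select_by_filter(self.per_model_totals(), energies,
                                   n_restraint=min(200, len(self.pool)),
                                   n_final=config.size_init)
            dinv6 = self.distances[list(idx)] ** -6.0
            one_sided = np.array([
                self.mode != "symmetric" and k == "upper_limit"
                for k in kinds
            ])
            score = _ensemble_score(dinv6.sum(axis=0), len(idx),
                                    np.asarray(d_obs), one_sided)
            state = EnsembleState(idx, score)
        else:
            raise SelectionError(f"unknown fit method {method!r}")
        return EnsembleFitResults(self, state, config, method, trace)


class EnsembleFitResults:
    """Selected ensemble with its restraint diagnostics."""

    def __init__(self, model: EnsembleNOEModel, state: EnsembleState,
                 config: SelectorConfig, method: str, trace):
        self.model = model
        self.state = state
        self.config = config
        self.method = method
        self.trace = trace

    @property
    def members(self):
        return [self.model.pool[i] for i in self.state.indices]

    @property
    def score(self) -> float:
        return self.state.score

    def restraint_table(self) -> pd.DataFrame:
        """Per-restraint d_obs, ensemble-averaged d*, residual."""
        idx = list(self.state.indices)
        dinv6 = self.model.distances[idx] ** -6.0
        d_star = (dinv6.mean(axis=0)) ** (-1.0 / 6.0)
        rows = []
        for j, r in enumerate(self.model.restraints):
            res = d_star[j] - r.d_obs
            if self.model.mode != "symmetric" and r.kind == "upper_limit":
                res = max(0.0, res)
            rows.append({
                "res_a": r.group_a.members[0][0],
                "atom_a": r.group_a.label or r.group_a.members[0][1],
                "res_b": r.group_b.members[0][0],
                "atom_b": r.group_b.label or r.group_b.members[0][1],
                "kind": r.kind,
                "d_obs": r.d_obs,
                "d_star": d_star[j],
                "residual": res,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        table = self.restraint_table()
        violated = int((table["residual"].abs() > 0.5).sum())
        lines = [
            "Ensemble NOE fit",
            "================",
            f"method:            {self.method}",
            f"pool size:         {len(self.model.pool)}",
            f"ensemble size:     {self.state.size}",
            f"members:           {list(self.state.indices)}",
            f"restraints:        {len(self.model.restraints)}",
            f"score (sum sq, A^2): {self.state.score:.4f}",
            f"rms residual (A):  "
            f"{float(np.sqrt(np.mean(table['residual'] ** 2))):.4f}",
            f"residuals > 0.5 A: {violated}",
        ]
        if self.method == "mc":
            lines.append(f"mc steps:          {self.config.steps}")
            lines.append(f"temperature:       {self.config.temperature}")
        return "\n".join(lines)
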