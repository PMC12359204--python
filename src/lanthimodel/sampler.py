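"""Candidate-pool generation: Ramachandran randomization, ring closure,
Metropolis refinement.

Two pipelines produce conformer pools:

* :func:`sample_unstructured` — for peptides without regular secondary
  structure: backbone torsions are drawn from the residue-type
  Ramachandran tables, thioether rings are closed by CCD trying closure
  orderings over permutations of the ring list, and the surviving models
  are ranked by the score function.
* :func:`sample_from_start` — for helical peptides: a user-supplied start
  structure is perturbed with the same Metropolis machinery at elevated
  move magnitudes, with rings re-closed after the large moves.

The score is a declared simplified potential (``SimpleScore``): soft-sphere
clash repulsion, Ramachandran table energies, a geometric backbone
hydrogen-bond reward and the thioether crosslink deviation penalty.  It
ranks conformers for pool assembly and keeps rings closed during
refinement; it is not a transferable force field.

Refinement (:func:`refine`) is Metropolis Monte Carlo with *small* moves
(one torsion) and *shear* moves (compensating phi(r) / psi(r-1) pair,
limiting lever-arm motion), run for a burn-in then a production phase;
the best conformer seen in production is returned.  Default counts are
desk-scale; ``FAITHFUL_SCHEDULE`` records the published protocol sizes
(150,000-200,000 models, 1000 burn-in + 9000 production steps, top 2.5%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .crosslink import CrosslinkGeometry, close_all_rings, measure_crosslink
from .geometry import Conformer, build_conformer, measure_phi_psi
from .topology import LanthipeptideTopology
from .torsions import table_for_residue

__all__ = [
    "SimpleScore",
    "SamplerConfig",
    "FAITHFUL_SCHEDULE",
    "SamplerError",
    "refine",
    "sample_unstructured",
    "sample_from_start",
    "sample_and_refine",
]


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimpleScore:
    """Weighted sum of clash, torsion, H-bond and crosslink terms."""

    clash_weight: float = 1.0
    torsion_weight: float = 0.2
    hbond_weight: float = 0.5
    crosslink_weight: float = 1.0
    clash_dmin_heavy: float = 2.8   # A, soft-sphere onset heavy-heavy
    clash_dmin_h: float = 2.0       # A, pairs involving hydrogen
    hbond_dmax: float = 2.5         # A, H...O
    hbond_amin: float = 120.0       # deg, N-H...O
    geometry: CrosslinkGeometry = field(default_factory=CrosslinkGeometry)

    def __post_init__(self) -> None:
        for w in (self.clash_weight, self.torsion_weight,
                  self.hbond_weight, self.crosslink_weight):
            if w < 0:
                raise ValueError("score weights must be non-negative")

    # -- terms --------------------------------------------------------------

    def clash(self, conformer: Conformer) -> float:
        coords = conformer.coords
        respos = np.array([p for p, _n, _e in conformer.atoms])
        is_h = np.array([e == "H" for _p, _n, e in conformer.atoms])
        d = squareform(pdist(coords))
        sep = np.abs(respos[:, None] - respos[None, :])
        dmin = np.where(is_h[:, None] | is_h[None, :],
                        self.clash_dmin_h, self.clash_dmin_heavy)
        eligible = sep >= 2
        # thioether-bonded residue pairs are covalently linked: exempt
        for ring in conformer.topology.rings:
            pa = respos == ring.donor_pos
            pb = respos == ring.acceptor_pos
            eligible &= ~(pa[:, None] & pb[None, :])
            eligible &= ~(pb[:, None] & pa[None, :])
        overlap = np.where(eligible & (d < dmin), dmin - d, 0.0)
        return float(np.sum(np.triu(overlap, 1) ** 2))

    def torsion(self, conformer: Conformer) -> float:
        pp = measure_phi_psi(conformer)
        total = 0.0
        for r in range(2, len(conformer.topology) + 1):
            spec = conformer.topology.residue(r)
            table = table_for_residue(spec.code, spec.chirality)
            total += table.score(pp[r - 1, 0], pp[r - 1, 1])
        return float(total)

    def hbond_count(self, conformer: Conformer) -> int:
        topo = conformer.topology
        n = len(topo)
        count = 0
        for i in range(1, n + 1):          # acceptor C=O of residue i
            o = conformer.xyz(i, "O")
            for j in range(1, n + 1):      # donor N-H of residue j
                if abs(i - j) < 3 or not conformer.has_atom(j, "H"):
                    continue
                h = conformer.xyz(j, "H")
                if np.linalg.norm(h - o) > self.hbond_dmax:
                    continue
                nn = conformer.xyz(j, "N")
                v1 = nn - h
                v2 = o - h
                cosa = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.rad2deg(np.arccos(np.clip(cosa, -1, 1)))
                if angle > self.hbond_amin:
                    count += 1
        return count

    def crosslink(self, conformer: Conformer) -> float:
        return float(sum(
            measure_crosslink(conformer, ring, self.geometry).total
            for ring in conformer.topology.rings
        ))

    def terms(self, conformer: Conformer) -> dict[str, float]:
        return {
            "clash": self.clash(conformer),
            "torsion": self.torsion(conformer),
            "hbond": -float(self.hbond_count(conformer)),
            "crosslink": self.crosslink(conformer),
        }

    def __call__(self, conformer: Conformer) -> float:
        t = self.terms(conformer)
        return (self.clash_weight * t["clash"]
                + self.torsion_weight * t["torsion"]
                + self.hbond_weight * t["hbond"]
                + self.crosslink_weight * t["crosslink"])


@dataclass(frozen=True)
class SamplerConfig:
    """Pool size, refinement schedule and move magnitudes."""

    n_models: int = 500
    burn_in: int = 100
    production: int = 400
    small_move_deg: float = 3.0
    shear_move_deg: float = 3.0
    large_move_deg: float = 15.0   # used by sample_from_start
    top_fraction: float = 0.025
    mc_temperature: float = 1.0
    ring_gap_reject: float = 0.5   # A, hard wall on C-S gap during moves
    max_ring_orderings: int = 24
    closure_tol: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_models <= 0:
            raise ValueError("n_models must be positive")
        if self.burn_in < 0 or self.production < 0:
            raise ValueError("schedule steps must be non-negative")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")


#: The published protocol sizes, for faithful (cluster-scale) runs.
FAITHFUL_SCHEDULE = SamplerConfig(
    n_models=150_000, burn_in=1000, production=9000, top_fraction=0.025)


def _rotatable_torsions(topology: LanthipeptideTopology):
    n = len(topology)
    out = [("psi", r) for r in range(1, n + 1)]
    out += [("phi", r) for r in range(2, n + 1)]
    return out


def _ring_gaps_ok(conformer: Conformer, geometry: CrosslinkGeometry,
                  limit: float) -> bool:
    for ring in conformer.topology.rings:
        cb = conformer.xyz(ring.donor_pos, "CB")
        sg = conformer.xyz(ring.acceptor_pos, "SG")
        if abs(np.linalg.norm(cb - sg) - geometry.cs_bond_length) > limit:
            return False
    return True


def refine(conformer: Conformer, score: SimpleScore | None = None,
           config: SamplerConfig | None = None,
           rng: np.random.Generator | None = None,
           small_deg: float | None = None) -> Conformer:
    """Metropolis refinement; returns the best conformer seen in production.

    The returned score is never worse than the input's (best-seen
    tracking).  Moves opening any thioether gap beyond
    ``config.ring_gap_reject`` are rejected outright; smaller strain is
    handled by the crosslink score term.
    """
    score = score or SimpleScore()
    config = config or SamplerConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mag = small_deg if small_deg is not None else config.small_move_deg

    torsions = _rotatable_torsions(conformer.topology)
    current = conformer.copy()
    current_score = score(current)
    best = current.copy()
    best_score = current_score

    total_steps = config.burn_in + config.production
    for step in range(total_steps):
        trial = current.copy()
        if rng.random() < 0.5 or len(conformer.topology) < 3:
            kind, res = torsions[int(rng.integers(len(torsions)))]
            trial.rotate_torsion(kind, res, rng.normal(0.0, mag))
        else:
            r = int(rng.integers(2, len(conformer.topology) + 1))
            delta = rng.normal(0.0, config.shear_move_deg)
            trial.rotate_torsion("phi", r, delta)
            trial.rotate_torsion("psi", r - 1, -delta)
        if not _ring_gaps_ok(trial, score.geometry, config.ring_gap_reject):
            continue
        trial_score = score(trial)
        delta_s = trial_score - current_score
        if delta_s <= 0 or rng.random() < np.exp(
                -delta_s / config.mc_temperature):
            current = trial
            current_score = trial_score
            if step >= config.burn_in and current_score < best_score:
                best = current.copy()
                best_score = current_score
    if current_score < best_score:  # end of burn-in with no production best
        best, best_score = current, current_score
    return best


def _ring_orderings(rings, config: SamplerConfig,
                    rng: np.random.Generator):
    rings = list(rings)
    if len(rings) <= 4:
        return list(itertools.permutations(rings))
    orderings = []
    for _ in range(config.max_ring_orderings):
        perm = list(rings)
        rng.shuffle(perm)
        orderings.append(tuple(perm))
    return orderings


def sample_unstructured(topology: LanthipeptideTopology,
                        config: SamplerConfig | None = None,
                        score: SimpleScore | None = None,
                        rng: np.random.Generator | None = None,
                        max_attempts_per_model: int = 3):
    """Generate a pool from Ramachandran-randomized backbones.

    For each model, torsions are drawn per residue from its table, the
    chain is built, and each thioether ring is closed; closure orderings
    are tried over permutations of the ring list until one succeeds.
    Models whose rings cannot be closed are dropped.  The returned pool is
    sorted by score, best first.

    Raises :class:`SamplerError` if no model survives.
    """
    config = config or SamplerConfig()
    score = score or SimpleScore()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(topology)
    tables = [table_for_residue(spec.code, spec.chirality)
              for spec in topology.residues]

    pool: list[Conformer] = []
    n_failed = 0
    for _model in range(config.n_models):
        built = None
        for _attempt in range(max_attempts_per_model):
            pp = np.empty((n, 2))
            for r in range(n):
                pp[r] = tables[r].sample(rng)
            conf = build_conformer(topology, pp)
            if not topology.rings:
                built = conf
                break
            for ordering in _ring_orderings(topology.rings, config, rng):
                closed, ok = close_all_rings(
                    conf, ordering, score.geometry, max_iter=40,
                    tol=config.closure_tol)
                if ok:
                    built = closed
                    break
            if built is not None:
                break
        if built is None:
            n_failed += 1
            continue
        pool.append(built)
    if not pool:
        raise SamplerError(
            f"all {config.n_models} models failed ring closure "
            f"({n_failed} drops); check the topology and geometry targets"
        )
    pool.sort(key=score)
    return pool


def sample_from_start(start: Conformer,
                      topology: LanthipeptideTopology,
                      config: SamplerConfig | None = None,
                      score: SimpleScore | None = None,
                      rng: np.random.Generator | None = None):
    """Generate a pool by perturbing a supplied start structure.

    Each model runs the Metropolis refinement at the elevated
    ``large_move_deg`` magnitude, then re-closes the rings.  With a
    zero-step schedule the pool is copies of the start.
    """
    config = config or SamplerConfig()
    score = score or SimpleScore()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if start.topology is not topology and \
            start.topology.sequence != topology.sequence:
        raise SamplerError("start structure does not match the topology")

    pool = []
    for _model in range(config.n_models):
        conf = refine(start, score, config, rng,
                      small_deg=config.large_move_deg)
        if topology.rings:
            conf, ok = close_all_rings(conf, topology.rings, score.geometry,
                                       max_iter=40, tol=config.closure_tol)
            if not ok:
                conf = start.copy()  # keep pool size; fall back to start
        pool.append(conf)
    return pool


def sample_and_refine(topology: LanthipeptideTopology,
                      config: SamplerConfig | None = None,
                      score: SimpleScore | None = None,
                      rng: np.random.Generator | None = None):
    """Two-stage schedule: sample, keep the top fraction, refine those.

    Returns ``(pool, stage_means)`` where stage_means are the mean scores
    of (initial pool, top fraction, refined pool) for monitoring that each
    stage improves on the last.
    """
    config = config or SamplerConfig()
    score = score or SimpleScore()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stage1 = sample_unstructured(topology, config, score, rng)
    scores1 = [score(c) for c in stage1]
    n_keep = max(1, int(round(config.top_fraction * len(stage1))))
    top = stage1[:n_keep]  # already sorted best-first
    scores_top = scores1[:n_keep]
    refined = [refine(c, score, config, rng) for c in top]
    scores2 = [score(c) for c in refined]
    refined_sorted = [c for _s, c in
                      sorted(zip(scores2, refined), key=lambda t: t[0])]
    means = (float(np.mean(scores1)), float(np.mean(scores_top)),
             float(np.mean(scores2)))
    return refined_sorted, means
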