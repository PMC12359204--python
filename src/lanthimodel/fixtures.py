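"""Deterministic synthetic fixtures: planted multi-state pools, NOE sets
computed from known mixtures, ring-flip atropisomer pairs.

Every fixture is a pure function of its recipe and seed — no external
files, bit-reproducible.  The default peptide is a 15-residue lanthipeptide
with two adjacent lanthionine rings and one dehydroalanine: small enough
for exhaustive selection oracles, rich enough to exercise ring logic.

The central fixture plants ``n_states`` distinct conformations (pairwise
backbone RMSD above a floor), hides them in a pool of decoys, and computes
NOE observations from the equal-weight r^-6 mixture of the planted states
plus Gaussian noise.  Selection methods should recover the planted states
from the pool given only the observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crosslink import close_all_rings
from .geometry import Conformer, backbone_rmsd
from .restraints import (
    NOERestraint,
    RestraintError,
    ensemble_average_distance,
    resolve_group,
    write_restraints_tsv,
)
from .sampler import SamplerConfig, sample_unstructured
from .topology import LanthipeptideTopology, RingSpec, parse_topology

__all__ = [
    "DEFAULT_TOPOLOGY_SPEC",
    "FixtureRecipe",
    "FixtureError",
    "default_topology",
    "random_conformers",
    "make_two_state_pool",
    "make_noe_set",
    "make_ring_flip",
    "write_fixture_dir",
]


class FixtureError(RuntimeError):
    pass


DEFAULT_TOPOLOGY_SPEC = """\
# 15-residue synthetic lanthipeptide: two adjacent rings, one Dha
seq AAGAACGAAGACA[DHA]A
ring 2-6 lan
ring 8-12 lan
"""


def default_topology() -> LanthipeptideTopology:
    return parse_topology(DEFAULT_TOPOLOGY_SPEC)


@dataclass(frozen=True)
class FixtureRecipe:
    """Everything needed to regenerate a planted-truth fixture."""

    topology_spec: str = DEFAULT_TOPOLOGY_SPEC
    n_states: int = 2
    n_decoys: int = 40
    decoy_perturbation_deg: float = 25.0
    noise_sd: float = 0.1
    n_restraints: int = 50
    min_state_rmsd: float = 1.0
    seed: int = 0

    @property
    def topology(self) -> LanthipeptideTopology:
        return parse_topology(self.topology_spec)


def random_conformers(topology: LanthipeptideTopology, n: int,
                      rng: np.random.Generator):
    """n ring-closed Ramachandran-random conformers."""
    return sample_unstructured(
        topology, SamplerConfig(n_models=n), rng=rng,
        max_attempts_per_model=6)


def _perturb(conformer: Conformer, magnitude_deg: float,
             rng: np.random.Generator, max_tries: int = 5):
    """Torsion-noise perturbation with ring re-closure; None on failure."""
    topo = conformer.topology
    for _ in range(max_tries):
        trial = conformer.copy()
        for r in range(1, len(topo) + 1):
            if r > 1:
                trial.rotate_torsion("phi", r, rng.normal(0, magnitude_deg))
            trial.rotate_torsion("psi", r, rng.normal(0, magnitude_deg))
        if not topo.rings:
            return trial
        closed, ok = close_all_rings(trial, topo.rings)
        if ok:
            return closed
    return None


def make_two_state_pool(recipe: FixtureRecipe | None = None):
    """Planted states + decoys, with ground-truth labels.

    Returns ``(pool, labels)`` where ``pool[i]`` has label ``"state_k"``
    for the planted states (always the first ``n_states`` entries) or
    ``"decoy_k"``.  Planted states are pairwise separated by more than
    ``min_state_rmsd`` backbone RMSD; decoys are torsion-noise
    perturbations of randomly chosen states.
    """
    recipe = recipe or FixtureRecipe()
    rng = np.random.default_rng(recipe.seed)
    topology = recipe.topology

    states: list[Conformer] = []
    for attempt in range(20):
        candidates = random_conformers(
            topology, recipe.n_states + 2 * attempt + 2, rng)
        states = []
        for c in candidates:
            if all(backbone_rmsd(c, s) > recipe.min_state_rmsd
                   for s in states):
                states.append(c)
            if len(states) == recipe.n_states:
                break
        if len(states) == recipe.n_states:
            break
    else:
        raise FixtureError(
            f"could not plant {recipe.n_states} states with pairwise "
            f"backbone RMSD > {recipe.min_state_rmsd} A"
        )

    decoys: list[Conformer] = []
    while len(decoys) < recipe.n_decoys:
        base = states[int(rng.integers(len(states)))]
        d = _perturb(base, recipe.decoy_perturbation_deg, rng)
        if d is not None:
            decoys.append(d)

    pool = states + decoys
    labels = ([f"state_{i}" for i in range(len(states))]
              + [f"decoy_{i}" for i in range(len(decoys))])
    return pool, labels


def _eligible_groups(topology: LanthipeptideTopology):
    """Per-residue NOE-active groups of the reduced atom set: amide H,
    alpha H, and methyl pseudoatoms."""
    groups = []
    for r in range(2, len(topology) + 1):  # residue 1 has no amide H
        spec = topology.residue(r)
        if spec.code not in ("PRO", "DPR"):
            groups.append((r, "H"))
        if spec.code == "GLY":
            groups.append((r, "QA"))
        elif not spec.alpha_sp2:
            groups.append((r, "HA"))
        if spec.code in ("ALA", "DAL"):
            groups.append((r, "MB"))
        elif spec.has_beta_methyl:
            groups.append((r, "MG"))
    return groups


def make_noe_set(subset, n_restraints: int, noise_sd: float,
                 rng: np.random.Generator,
                 kind: str = "target",
                 d_min: float = 1.8, d_max: float = 7.0):
    """NOE observations computed from the equal-weight mixture of
    ``subset`` via the r^-6 ensemble average, plus Gaussian noise
    (observations floored at 0.5 A).

    Only pairs whose mixture distance falls in the NOE-observable window
    ``(d_min, d_max)`` and whose residues are separated by at least two
    positions are eligible.
    """
    subset = list(subset)
    if not subset:
        raise RestraintError("empty subset")
    topology = subset[0].topology
    groups = _eligible_groups(topology)
    candidates = []
    for i, (ra, aa) in enumerate(groups):
        for rb, ab in groups[i + 1:]:
            if abs(ra - rb) < 2:
                continue
            restraint = NOERestraint(
                resolve_group(topology, ra, aa),
                resolve_group(topology, rb, ab),
                d_obs=1.0, kind=kind)
            d_true = ensemble_average_distance(subset, restraint)
            if d_min < d_true < d_max:
                candidates.append((restraint, d_true))
    if not candidates:
        raise RestraintError("no eligible NOE pairs in the subset")
    n_take = min(n_restraints, len(candidates))
    picks = rng.choice(len(candidates), size=n_take, replace=False)
    out = []
    for p in sorted(picks):
        restraint, d_true = candidates[p]
        d_obs = max(0.5, d_true + rng.normal(0.0, noise_sd))
        out.append(NOERestraint(restraint.group_a, restraint.group_b,
                                d_obs, kind))
    return out


def make_ring_flip(conformer: Conformer, ring: RingSpec) -> Conformer:
    """Mirror the ring-span atoms through the ring's best-fit plane.

    Reflection is an isometry of the span subset, so intra-ring bond
    lengths, bond angles and the thioether closure are preserved while
    chirality-dependent signs flip — producing the opposite atropisomer
    for probes that straddle the ring.  Atoms outside the span do not
    move; the peptide-bond geometry at the span boundary inherits a small
    seam strain from the reflection, acceptable in a classification
    fixture.  The flip is an involution: flipping twice restores the
    original coordinates.
    """
    lo, hi = ring.span
    flipped = conformer.copy()
    span_idx = np.array([i for i, (p, _n, _e) in enumerate(conformer.atoms)
                         if lo <= p <= hi])
    pts = flipped.coords[span_idx]
    center = pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(pts - center)
    normal = vt[2]
    dist = (pts - center) @ normal
    flipped.coords[span_idx] = pts - 2.0 * dist[:, None] * normal
    return flipped


def write_fixture_dir(recipe: FixtureRecipe, outdir) -> dict[str, Path]:
    """Materialize a self-contained fixture directory: topology, pool PDB,
    restraints TSV (from the planted-state mixture) and labels TSV."""
    from .pdbio import write_ensemble
    from .topology import serialize_topology

    recipe = recipe or FixtureRecipe()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(recipe.seed + 1)
    pool, labels = make_two_state_pool(recipe)
    restraints = make_noe_set(
        pool[:recipe.n_states], recipe.n_restraints, recipe.noise_sd, rng)

    paths = {
        "topology": outdir / "topology.txt",
        "pool": outdir / "pool.pdb",
        "restraints": outdir / "restraints.tsv",
        "labels": outdir / "labels.tsv",
    }
    paths["topology"].write_text(serialize_topology(recipe.topology))
    write_ensemble(pool, paths["pool"],
                   remarks=[f"synthetic fixture seed={recipe.seed}"])
    paths["restraints"].write_text(write_restraints_tsv(restraints))
    paths["labels"].write_text(
        "# model\tlabel\n"
        + "".join(f"{i + 1}\t{lab}\n" for i, lab in enumerate(labels)))
    return paths
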