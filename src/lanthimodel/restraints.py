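"""NOE distance restraints and r^-6 ensemble-averaged scoring.

An NOE restraint couples two (possibly ambiguous) proton groups with an
observed distance.  Within one conformer, an ambiguous group pair
collapses to the effective distance

    d_eff = ( sum over cross-pairs d^-6 )^(-1/6)

(the standard pseudoatom r^-6 *sum*, which shortens the distance for
multi-proton groups), while across an ensemble of N equally populated
conformers the averaged distance is

    d* = ( (1/N) * sum_i d_i^-6 )^(-1/6)

the r^-6 *mean* over states.  Short distances in any single member
dominate d*, which is what lets a flexible ensemble satisfy restraints no
single conformer can.

Upper-limit restraints contribute one-sided residuals max(0, d* - d_obs);
``mode="symmetric"`` scores every restraint as a two-sided target instead.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import Conformer
from .topology import LanthipeptideTopology

__all__ = [
    "AtomGroup",
    "NOERestraint",
    "RestraintRow",
    "RestraintScore",
    "RestraintError",
    "effective_distance",
    "ensemble_average_distance",
    "score_ensemble",
    "restraint_distance_matrix",
    "parse_restraints_tsv",
    "parse_upl",
    "write_restraints_tsv",
]


class RestraintError(ValueError):
    pass


@functools.lru_cache(maxsize=1)
def _pseudoatom_map() -> dict[tuple[str, str], tuple[str, ...]]:
    text = (resources.files("lanthimodel.data") / "pseudoatoms.tsv").read_text()
    out: dict[tuple[str, str], tuple[str, ...]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        code, pseudo, members = line.split("\t")
        out[(code, pseudo)] = tuple(members.split(","))
    return out


@dataclass(frozen=True)
class AtomGroup:
    """A non-empty set of equivalent atoms; one side of a restraint."""

    members: tuple[tuple[int, str], ...]  # (residue position, atom name)
    label: str | None = None              # pseudoatom name, if expanded

    def __post_init__(self) -> None:
        if not self.members:
            raise RestraintError("empty atom group")

    def coords(self, conformer: Conformer) -> np.ndarray:
        return np.array([conformer.xyz(p, n) for p, n in self.members])


def resolve_group(topology: LanthipeptideTopology, position: int,
                  atom: str) -> AtomGroup:
    """Build an AtomGroup from a restraint-file atom field, expanding
    pseudoatom names (MB, MG, QA, ...) and normalizing HN -> H."""
    code = topology.residue(position).code
    name = "H" if atom.upper() == "HN" else atom.upper()
    expansion = _pseudoatom_map().get((code, name))
    if expansion is not None:
        return AtomGroup(tuple((position, a) for a in expansion), label=name)
    return AtomGroup(((position, name),))


@dataclass(frozen=True)
class NOERestraint:
    group_a: AtomGroup
    group_b: AtomGroup
    d_obs: float
    kind: str = "upper_limit"  # or "target"

    def __post_init__(self) -> None:
        if self.d_obs <= 0:
            raise RestraintError("observed distance must be positive")
        if self.kind not in ("upper_limit", "target"):
            raise RestraintError(f"unknown restraint kind {self.kind!r}")
        if set(self.group_a.members) & set(self.group_b.members):
            raise RestraintError("restraint groups must be disjoint")


def effective_distance(conformer: Conformer, group_a: AtomGroup,
                       group_b: AtomGroup) -> float:
    """r^-6 sum over all cross-pairs; a plain distance for 1x1 groups."""
    ca = group_a.coords(conformer)
    cb = group_b.coords(conformer)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    if np.any(d < 1e-9):
        raise RestraintError("coincident atoms across restraint groups")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def ensemble_average_distance(members, restraint: NOERestraint) -> float:
    """Eq-style r^-6 mean over N equally populated conformers."""
    members = list(members)
    if not members:
        raise RestraintError("empty ensemble")
    d = np.array([effective_distance(m, restraint.group_a, restraint.group_b)
                  for m in members])
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


@dataclass(frozen=True)
class RestraintRow:
    d_star: float
    residual: float          # signed for targets, >= 0 for upper limits

    @property
    def squared(self) -> float:
        return self.residual ** 2


@dataclass(frozen=True)
class RestraintScore:
    rows: tuple[RestraintRow, ...]

    @property
    def total(self) -> float:
        return float(sum(r.squared for r in self.rows))


def _residual(d_star: float, restraint: NOERestraint, mode: str) -> float:
    if mode == "symmetric" or restraint.kind == "target":
        return d_star - restraint.d_obs
    return max(0.0, d_star - restraint.d_obs)


def score_ensemble(members, restraints, mode: str = "kind_aware"
                   ) -> RestraintScore:
    """Sum of squared deviations between d* and the observations."""
    if mode not in ("kind_aware", "symmetric"):
        raise RestraintError(f"unknown scoring mode {mode!r}")
    members = list(members)
    restraints = list(restraints)
    if not members or not restraints:
        raise RestraintError("need at least one member and one restraint")
    rows = []
    for r in restraints:
        d_star = ensemble_average_distance(members, r)
        rows.append(RestraintRow(d_star, _residual(d_star, r, mode)))
    return RestraintScore(tuple(rows))


def restraint_distance_matrix(pool, restraints) -> np.ndarray:
    """(n_pool, n_restraints) per-conformer effective distances; the input
    to ensemble selection, computed once per pool."""
    pool = list(pool)
    restraints = list(restraints)
    out = np.empty((len(pool), len(restraints)))
    for i, conf in enumerate(pool):
        for j, r in enumerate(restraints):
            out[i, j] = effective_distance(conf, r.group_a, r.group_b)
    return out


# ---------------------------------------------------------------------------
# File formats


def parse_restraints_tsv(text: str, topology: LanthipeptideTopology
                         ) -> list[NOERestraint]:
    """Tabular format: resA atomA resB atomB distance [kind].

    Whitespace-separated; ``#`` comments; atom fields accept pseudoatom
    names; kind defaults to upper_limit.
    """
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split()
        if f[0].lower() in ("resa", "res_a"):  # optional header row
            continue
        if len(f) not in (5, 6):
            raise RestraintError(
                f"line {lineno}: expected 5 or 6 fields, got {len(f)}"
            )
        try:
            res_a, res_b = int(f[0]), int(f[2])
            dist = float(f[4])
        except ValueError as exc:
            raise RestraintError(f"line {lineno}: {exc}") from exc
        kind = f[5] if len(f) == 6 else "upper_limit"
        out.append(NOERestraint(
            resolve_group(topology, res_a, f[1]),
            resolve_group(topology, res_b, f[3]),
            dist, kind,
        ))
    return out


def parse_upl(text: str, topology: LanthipeptideTopology
              ) -> list[NOERestraint]:
    """CYANA-style .upl: resnumA resnameA atomA resnumB resnameB atomB dist.

    Residue names are accepted but positions are authoritative; every
    restraint is an upper limit.
    """
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split()
        if len(f) < 7:
            raise RestraintError(
                f"line {lineno}: expected 7 fields in .upl row"
            )
        try:
            res_a, res_b = int(f[0]), int(f[3])
            dist = float(f[6])
        except ValueError as exc:
            raise RestraintError(f"line {lineno}: {exc}") from exc
        out.append(NOERestraint(
            resolve_group(topology, res_a, f[2]),
            resolve_group(topology, res_b, f[5]),
            dist, "upper_limit",
        ))
    return out


def write_restraints_tsv(restraints) -> str:
    lines = ["# resA atomA resB atomB distance kind"]
    for r in restraints:
        pa, na = r.group_a.members[0]
        pb, nb = r.group_b.members[0]
        na = r.group_a.label or na
        nb = r.group_b.label or nb
        lines.append(f"{pa}\t{na}\t{pb}\t{nb}\t{r.d_obs:.3f}\t{r.kind}")
    return "\n".join(lines) + "\n"
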