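"""Atropisomer classification by plane-side sign tests.

Lanthipeptides with overlapping rings can be kinetically trapped in
non-interconvertible conformer classes (atropisomers), e.g. with one ring
threaded on either side of another.  Classes are told apart geometrically:
pick three alpha carbons on nearby residues of a loop of interest (they
define a plane) and a fourth alpha carbon on a different loop; the sign of
the probe's position along the plane normal is a pseudoscalar — invariant
under proper rigid motion, negated by mirroring — so a vector of such
signs partitions a pool into classes that cannot interconvert by
continuous motion without crossing the plane.

Probe quads are chosen by the user per peptide; :func:`suggest_probes`
offers a heuristic starting set (ring-based planes probed from other
rings) but is no substitute for inspection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .geometry import Conformer, GeometryError
from .topology import LanthipeptideTopology

__all__ = [
    "ProbeQuad",
    "AtropisomerKey",
    "DegenerateProbeError",
    "probe_sign",
    "classify",
    "filter_pool",
    "suggest_probes",
    "parse_probes",
]


class DegenerateProbeError(GeometryError):
    """Probe geometry too close to planar/collinear to give a sign."""


#: minimum |signed distance| (A) of the probe from the plane
DEFAULT_TOLERANCE = 0.1


@dataclass(frozen=True)
class ProbeQuad:
    """Three plane residues plus one probe residue (alpha carbons, 1-based)."""

    plane: tuple[int, int, int]
    probe: int

    def __post_init__(self) -> None:
        if len({*self.plane, self.probe}) != 4:
            raise ValueError("probe quad needs four distinct residues")


AtropisomerKey = tuple[int, ...]


def probe_sign(conformer: Conformer, quad: ProbeQuad,
               tolerance: float = DEFAULT_TOLERANCE) -> int:
    """+1 or -1: which side of the plane the probe alpha carbon lies on.

    The sign is that of (probe - p1) . ((p2 - p1) x (p3 - p1)).
    """
    p1, p2, p3 = (conformer.xyz(r, "CA") for r in quad.plane)
    probe = conformer.xyz(quad.probe, "CA")
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    if norm < 1e-8:
        raise DegenerateProbeError(
            f"plane residues {quad.plane} are collinear"
        )
    signed_dist = float((probe - p1) @ (normal / norm))
    if abs(signed_dist) < tolerance:
        raise DegenerateProbeError(
            f"probe {quad.probe} within {tolerance} A of plane "
            f"{quad.plane} (signed distance {signed_dist:.3f})"
        )
    return 1 if signed_dist > 0 else -1


def classify(conformer: Conformer, probes,
             tolerance: float = DEFAULT_TOLERANCE) -> AtropisomerKey:
    """Concatenated probe signs; the conformer's atropisomer key."""
    probes = list(probes)
    if not probes:
        raise ValueError("need at least one probe quad")
    return tuple(probe_sign(conformer, q, tolerance) for q in probes)


def filter_pool(pool, probes, reference="majority",
                tolerance: float = DEFAULT_TOLERANCE):
    """Keep pool members in one atropisomer class.

    ``reference`` is an explicit key or ``"majority"`` (keep the modal
    class; a tie raises, requiring an explicit choice).  Returns
    ``(filtered_pool, census)`` with per-class counts; census counts sum
    to the pool size.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty pool")
    keys = [classify(c, probes, tolerance) for c in pool]
    census = Counter(keys)
    if reference == "majority":
        ranked = census.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            tied = [k for k, v in ranked if v == ranked[0][1]]
            raise ValueError(
                f"majority tie between classes {tied}; pass an explicit "
                "reference key"
            )
        reference = ranked[0][0]
    else:
        reference = tuple(reference)
    filtered = [c for c, k in zip(pool, keys) if k == reference]
    return filtered, dict(census)


def suggest_probes(topology: LanthipeptideTopology) -> list[ProbeQuad]:
    """Heuristic probe set: for each ring pair, a plane from one ring's
    donor/midpoint/acceptor probed by the other ring's midpoint residue.

    A starting point only — probe choice is structural judgement.
    """
    rings = topology.rings
    if len(rings) < 2:
        return []
    probes = []
    for a in rings:
        lo, hi = a.span
        mid = (lo + hi) // 2
        plane = (lo, mid, hi)
        if len(set(plane)) != 3:
            continue
        for b in rings:
            if b is a:
                continue
            blo, bhi = b.span
            bmid = (blo + bhi) // 2
            if bmid in plane:
                continue
            probes.append(ProbeQuad(plane, bmid))
    return probes


def ring_probe(conformer: Conformer, ring,
               tolerance: float = DEFAULT_TOLERANCE) -> ProbeQuad:
    """A probe quad entirely within one ring's span.

    Plane: donor, midpoint and acceptor alpha carbons; probe: the span
    residue farthest off that plane.  Because all four residues lie in the
    span, any transform that mirrors the span (a ring flip) negates this
    probe's sign exactly — the sensitive detector for flip fixtures, and a
    complement to the cross-loop quads used for threading atropisomers.
    """
    lo, hi = ring.span
    mid = (lo + hi) // 2
    plane = (lo, mid, hi)
    p1, p2, p3 = (conformer.xyz(r, "CA") for r in plane)
    normal = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(normal)
    if norm < 1e-8:
        raise DegenerateProbeError(f"plane residues {plane} are collinear")
    normal /= norm
    best, best_dist = None, 0.0
    for r in range(lo, hi + 1):
        if r in plane:
            continue
        d = abs(float((conformer.xyz(r, "CA") - p1) @ normal))
        if d > best_dist:
            best, best_dist = r, d
    if best is None or best_dist < tolerance:
        raise DegenerateProbeError(
            f"no span residue of ring {lo}-{hi} is off-plane by {tolerance} A"
        )
    return ProbeQuad(plane, best)


def parse_probes(text: str) -> list[ProbeQuad]:
    """Parse probe config lines: ``plane: i,j,k probe: m`` (1-based)."""
    probes = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            plane_part, probe_part = line.split("probe:")
            plane_vals = plane_part.replace("plane:", "").strip()
            i, j, k = (int(x) for x in plane_vals.split(","))
            m = int(probe_part.strip())
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad probe spec {raw!r}") from exc
        probes.append(ProbeQuad((i, j, k), m))
    return probes
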