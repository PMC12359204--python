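"""Lanthipeptide topology: sequence, thioether rings, dehydrations.

A lanthipeptide core peptide is described by its residue sequence
(canonical amino acids plus dehydroalanine/dehydrobutyrine and D-amino
acids) together with the lanthionine / methyllanthionine rings that
crosslink a formerly dehydrated residue (the *donor*) to a cysteine-derived
residue (the *acceptor*) through a C-S thioether bond.  The topology is the
single source of truth for residue connectivity; conformers, restraints and
samplers all refer back to it.

Residue positions are 1-based everywhere in the public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ResidueSpec",
    "RingSpec",
    "LanthipeptideTopology",
    "TopologyError",
    "parse_topology",
    "serialize_topology",
    "classify_ring_pair",
    "helix_compatible",
]


class TopologyError(ValueError):
    """Raised for malformed topology text or invariant violations."""


# one-letter -> three-letter, canonical L-amino acids
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_CANONICAL = set(_ONE_TO_THREE.values())

# PDB chemical-component codes for D-amino acids -> parent L code
_D_CODES = {
    "DAL": "ALA", "DAR": "ARG", "DSG": "ASN", "DAS": "ASP", "DCY": "CYS",
    "DGN": "GLN", "DGL": "GLU", "DHI": "HIS", "DIL": "ILE", "DLE": "LEU",
    "DLY": "LYS", "MED": "MET", "DPN": "PHE", "DPR": "PRO", "DSN": "SER",
    "DTH": "THR", "DTR": "TRP", "DTY": "TYR", "DVA": "VAL",
}

# noncanonical residues produced by lanthipeptide maturation
_DEHYDRO = {"DHA", "DHB"}          # sp2 alpha carbon, achiral
_ABU_LIKE = {"ABU", "DBB"}         # 2-aminobutanoic acid (L / D)

_KNOWN_CODES = _CANONICAL | set(_D_CODES) | _DEHYDRO | _ABU_LIKE

# residues carrying a beta-methyl (CG on CB): valid methyllanthionine donors
_BETA_METHYL = {"ABU", "DBB", "DHB", "THR", "DTH"}


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of the core peptide.

    ``alpha_sp2`` marks dehydro residues (Dha/Dhb) whose planar alpha
    carbon removes backbone chirality; such residues are always achiral.
    """

    position: int
    code: str
    alpha_sp2: bool = False
    chirality: str = "L"  # {"L", "D", "achiral"}

    def __post_init__(self) -> None:
        if self.code not in _KNOWN_CODES:
            raise TopologyError(f"unknown residue code {self.code!r}")
        if self.alpha_sp2 and self.chirality != "achiral":
            raise TopologyError(
                f"residue {self.position} ({self.code}): sp2 alpha carbon "
                "implies achiral backbone"
            )

    @property
    def has_beta_methyl(self) -> bool:
        return self.code in _BETA_METHYL


@dataclass(frozen=True)
class RingSpec:
    """One thioether ring: donor (formerly dehydrated) -> acceptor (Cys).

    ``ring_type`` is ``"lanthionine"`` (Dha-derived donor) or
    ``"methyllanthionine"`` (Dhb/Thr-derived donor with a beta-methyl).
    ``bridge_chirality`` labels the stereochemistry of the bridge carbons;
    the DL configuration is the most common and is the default.
    """

    donor_pos: int
    acceptor_pos: int
    ring_type: str
    bridge_chirality: str = "DL"

    def __post_init__(self) -> None:
        if self.donor_pos == self.acceptor_pos:
            raise TopologyError("ring donor and acceptor must differ")
        if self.ring_type not in ("lanthionine", "methyllanthionine"):
            raise TopologyError(f"unknown ring type {self.ring_type!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive sequence interval covered by the ring."""
        lo = min(self.donor_pos, self.acceptor_pos)
        hi = max(self.donor_pos, self.acceptor_pos)
        return lo, hi


@dataclass(frozen=True)
class LanthipeptideTopology:
    residues: tuple[ResidueSpec, ...]
    rings: tuple[RingSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n == 0:
            raise TopologyError("empty sequence")
        for i, r in enumerate(self.residues, start=1):
            if r.position != i:
                raise TopologyError(
                    f"residue positions must be 1..{n} in order; "
                    f"got {r.position} at slot {i}"
                )
        donors: set[int] = set()
        acceptors: set[int] = set()
        for ring in self.rings:
            for pos, role in ((ring.donor_pos, "donor"),
                              (ring.acceptor_pos, "acceptor")):
                if not 1 <= pos <= n:
                    raise TopologyError(
                        f"ring {role} position {pos} out of range 1..{n}"
                    )
            if ring.donor_pos in donors:
                raise TopologyError(
                    f"residue {ring.donor_pos} is donor in two rings"
                )
            if ring.acceptor_pos in acceptors:
                raise TopologyError(
                    f"residue {ring.acceptor_pos} is acceptor in two rings"
                )
            donors.add(ring.donor_pos)
            acceptors.add(ring.acceptor_pos)
            # acceptor is normally cysteine-derived; tolerated otherwise at
            # parse time (geometry errors later if no SG can be built)
            don = self.residues[ring.donor_pos - 1]
            if ring.ring_type == "methyllanthionine" and not don.has_beta_methyl:
                raise TopologyError(
                    f"methyllanthionine donor at {ring.donor_pos} must carry "
                    f"a beta-methyl (Thr/Dhb/Abu-derived), got {don.code}"
                )
        # the same atom may not sit in two thioether bonds
        if donors & acceptors:
            clash = sorted(donors & acceptors)
            raise TopologyError(
                f"residue(s) {clash} would participate in two thioether bonds"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.residues)

    def residue(self, position: int) -> ResidueSpec:
        if not 1 <= position <= len(self.residues):
            raise TopologyError(f"position {position} out of range")
        return self.residues[position - 1]

    def ring_for_donor(self, position: int) -> RingSpec | None:
        for ring in self.rings:
            if ring.donor_pos == position:
                return ring
        return None

    def ring_for_acceptor(self, position: int) -> RingSpec | None:
        for ring in self.rings:
            if ring.acceptor_pos == position:
                return ring
        return None


def _residue_from_code(position: int, code: str) -> ResidueSpec:
    if code in _DEHYDRO:
        return ResidueSpec(position, code, alpha_sp2=True, chirality="achiral")
    if code == "GLY":
        return ResidueSpec(position, code, chirality="achiral")
    if code in _D_CODES or code == "DBB":
        return ResidueSpec(position, code, chirality="D")
    return ResidueSpec(position, code, chirality="L")


def _parse_sequence(seq: str, lineno: int) -> list[ResidueSpec]:
    residues: list[ResidueSpec] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch == "[":
            j = seq.find("]", i)
            if j < 0:
                raise TopologyError(
                    f"line {lineno}: unterminated '[' in sequence"
                )
            code = seq[i + 1 : j].upper()
            if code not in _KNOWN_CODES:
                raise TopologyError(
                    f"line {lineno}: unknown residue code [{code}]"
                )
            i = j + 1
        else:
            code = _ONE_TO_THREE.get(ch.upper())
            if code is None:
                raise TopologyError(
                    f"line {lineno}: unknown one-letter code {ch!r}"
                )
            i += 1
        residues.append(_residue_from_code(len(residues) + 1, code))
    if not residues:
        raise TopologyError(f"line {lineno}: empty sequence")
    return residues


_RING_TYPES = {"lan": "lanthionine", "melan": "methyllanthionine"}
_RING_TYPES_INV = {v: k for k, v in _RING_TYPES.items()}


def parse_topology(text: str) -> LanthipeptideTopology:
    """Parse the line-oriented topology format.

    ::

        # comment
        seq AAGA[DHA]C
        ring 2-6 lan
        ring 5-9 melan DL

    ``seq`` takes a one-letter string with bracketed three-letter codes for
    noncanonical residues; ``ring`` takes ``<donor>-<acceptor> <lan|melan>``
    with an optional bridge-chirality label.
    """
    residues: list[ResidueSpec] | None = None
    rings: list[RingSpec] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        keyword = fields[0].lower()
        if keyword == "seq":
            if residues is not None:
                raise TopologyError(f"line {lineno}: duplicate seq line")
            if len(fields) != 2:
                raise TopologyError(f"line {lineno}: seq takes one field")
            residues = _parse_sequence(fields[1], lineno)
        elif keyword == "ring":
            if len(fields) not in (3, 4):
                raise TopologyError(
                    f"line {lineno}: ring takes '<d>-<a> <lan|melan> [chir]'"
                )
            try:
                d_s, a_s = fields[1].split("-")
                donor, acceptor = int(d_s), int(a_s)
            except ValueError as exc:
                raise TopologyError(
                    f"line {lineno}: bad ring positions {fields[1]!r}"
                ) from exc
            ring_type = _RING_TYPES.get(fields[2].lower())
            if ring_type is None:
                raise TopologyError(
                    f"line {lineno}: ring type must be lan or melan, "
                    f"got {fields[2]!r}"
                )
            chirality = fields[3].upper() if len(fields) == 4 else "DL"
            rings.append(RingSpec(donor, acceptor, ring_type, chirality))
        else:
            raise TopologyError(f"line {lineno}: unknown keyword {keyword!r}")
    if residues is None:
        raise TopologyError("no seq line found")
    return LanthipeptideTopology(tuple(residues), tuple(rings))


_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}


def serialize_topology(topology: LanthipeptideTopology) -> str:
    """Inverse of :func:`parse_topology` (round-trips exactly)."""
    parts = []
    for r in topology.residues:
        one = _THREE_TO_ONE.get(r.code)
        parts.append(one if one is not None else f"[{r.code}]")
    lines = [f"seq {''.join(parts)}"]
    for ring in topology.rings:
        lines.append(
            f"ring {ring.donor_pos}-{ring.acceptor_pos} "
            f"{_RING_TYPES_INV[ring.ring_type]} {ring.bridge_chirality}"
        )
    return "\n".join(lines) + "\n"


def classify_ring_pair(a: RingSpec, b: RingSpec) -> str:
    """Classify two rings of one topology as adjacent, overlapping or nested.

    Ring spans are the inclusive intervals between donor and acceptor.
    *Adjacent* rings occupy disjoint intervals, *nested* rings have one
    interval strictly inside the other, and *overlapping* rings interleave.
    """
    lo_a, hi_a = a.span
    lo_b, hi_b = b.span
    if (lo_a, hi_a) == (lo_b, hi_b):
        raise TopologyError("identical ring spans are degenerate")
    if hi_a < lo_b or hi_b < lo_a:
        return "adjacent"
    if (lo_a < lo_b and hi_b < hi_a) or (lo_b < lo_a and hi_a < hi_b):
        return "nested"
    return "overlapping"


def helix_compatible(ring: RingSpec) -> bool:
    """Whether the ring geometry is compatible with an alpha helix.

    Rings whose acceptor cysteine sits three or four residues past the
    donor span roughly one helical turn and can cap or stabilize a helix;
    wider or reversed rings cannot.
    """
    return ring.acceptor_pos - ring.donor_pos in (3, 4)
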