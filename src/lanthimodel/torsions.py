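"""Per-residue-type (phi, psi) potentials: storage, scoring, sampling.

Tables are periodic grids of backbone-torsion energies in arbitrary
kcal/mol-like units, with a boolean mask marking disallowed cells (masked
cells have sampling probability zero regardless of their energy).  The
package ships coarse tables for the canonical general case, glycine, and
the dehydro residues Dha and Dhb.  The dehydro tables reflect the planar
sp2 alpha carbon, which makes the potential symmetric under
(phi, psi) -> (-phi, -psi); the Dhb table is additionally restricted where
the gamma methyl would clash with the backbone, so its allowed region is a
strict subset of Dha's.

The shipped tables are qualitative, documented analytic surfaces
regenerated by ``scripts/make_rama_tables.py``; users with quantum-chemical
scans can substitute their own files in the same format.

D-amino acids score through the mirrored general table; sampling draws a
grid cell with Boltzmann weight exp(-E/T) and jitters uniformly within the
cell.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "TorsionTable",
    "TorsionTableError",
    "load_table",
    "table_for_residue",
    "score_torsion",
    "sample_torsion",
]


class TorsionTableError(ValueError):
    pass


@dataclass(frozen=True)
class TorsionTable:
    """Periodic (phi, psi) energy grid with a disallowed mask.

    Nodes sit at ``-180 + spacing * i`` for ``i in range(n)``,
    ``n = 360 / spacing``; values wrap periodically in both axes.
    """

    code: str
    spacing: float
    energies: np.ndarray  # (n, n), energies[i, j] at (phi_i, psi_j)
    mask: np.ndarray      # (n, n) bool, True = disallowed

    def __post_init__(self) -> None:
        n = int(round(360.0 / self.spacing))
        if abs(n * self.spacing - 360.0) > 1e-9:
            raise TorsionTableError("spacing must divide 360")
        if self.energies.shape != (n, n) or self.mask.shape != (n, n):
            raise TorsionTableError("grid shape does not match spacing")
        if not np.all(np.isfinite(self.energies)):
            raise TorsionTableError("table energies must be finite")

    @property
    def n(self) -> int:
        return self.energies.shape[0]

    @property
    def nodes(self) -> np.ndarray:
        return -180.0 + self.spacing * np.arange(self.n)

    def mirrored(self) -> "TorsionTable":
        """Table with E'(phi, psi) = E(-phi, -psi) — scores D-residues."""
        # node at -x lives at index (n - i) % n: reverse both axes, roll by 1
        e = np.roll(np.roll(self.energies[::-1, ::-1], 1, axis=0), 1, axis=1)
        m = np.roll(np.roll(self.mask[::-1, ::-1], 1, axis=0), 1, axis=1)
        return TorsionTable(self.code + "_D", self.spacing, e, m)

    def cell_index(self, phi, psi):
        """Nearest-node index pair for (phi, psi), wrapped periodically."""
        i = np.round((np.asarray(phi) + 180.0) / self.spacing).astype(int)
        j = np.round((np.asarray(psi) + 180.0) / self.spacing).astype(int)
        return i % self.n, j % self.n

    # -- scoring ------------------------------------------------------------

    def score(self, phi, psi):
        """Periodic bilinear interpolation; exact at grid nodes."""
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        x = (phi + 180.0) / self.spacing
        y = (psi + 180.0) / self.spacing
        i0 = np.floor(x).astype(int) % self.n
        j0 = np.floor(y).astype(int) % self.n
        i1 = (i0 + 1) % self.n
        j1 = (j0 + 1) % self.n
        fx = x - np.floor(x)
        fy = y - np.floor(y)
        e = self.energies
        val = (e[i0, j0] * (1 - fx) * (1 - fy)
               + e[i1, j0] * fx * (1 - fy)
               + e[i0, j1] * (1 - fx) * fy
               + e[i1, j1] * fx * fy)
        return val if val.shape else float(val)

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: np.random.Generator, temperature: float = 1.0,
               size: int | None = None):
        """Draw (phi, psi) with cell probability ∝ exp(-E/T) over allowed
        cells, uniform within the cell.  Never returns a masked cell."""
        allowed = ~self.mask
        if not allowed.any():
            raise TorsionTableError(
                f"table {self.code}: all cells masked, cannot sample"
            )
        if temperature <= 0:
            raise TorsionTableError("sampling temperature must be positive")
        e = self.energies[allowed]
        w = np.exp(-(e - e.min()) / temperature)
        p = w / w.sum()
        flat = np.flatnonzero(allowed.ravel())
        m = 1 if size is None else size
        picks = rng.choice(flat, size=m, p=p)
        i, j = np.unravel_index(picks, self.energies.shape)
        half = self.spacing / 2.0
        phi = self.nodes[i] + rng.uniform(-half, half, m)
        psi = self.nodes[j] + rng.uniform(-half, half, m)
        phi = (phi + 180.0) % 360.0 - 180.0
        psi = (psi + 180.0) % 360.0 - 180.0
        if size is None:
            return float(phi[0]), float(psi[0])
        return phi, psi


# ---------------------------------------------------------------------------
# File format: header lines (code, spacing) then "phi psi energy masked" rows


def loads(text: str) -> TorsionTable:
    code = None
    spacing = None
    rows = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if fields[0] == "code":
            code = fields[1]
        elif fields[0] == "spacing":
            spacing = float(fields[1])
        elif fields[0] == "phi":  # column header
            continue
        else:
            if len(fields) != 4:
                raise TorsionTableError(f"bad table row: {raw!r}")
            rows.append((float(fields[0]), float(fields[1]),
                         float(fields[2]), int(fields[3])))
    if code is None or spacing is None:
        raise TorsionTableError("table file missing code/spacing header")
    n = int(round(360.0 / spacing))
    if len(rows) != n * n:
        raise TorsionTableError(
            f"expected {n * n} rows for spacing {spacing}, got {len(rows)}"
        )
    energies = np.full((n, n), np.nan)
    mask = np.zeros((n, n), bool)
    for phi, psi, e, m in rows:
        i = int(round((phi + 180.0) / spacing)) % n
        j = int(round((psi + 180.0) / spacing)) % n
        energies[i, j] = e
        mask[i, j] = bool(m)
    if np.isnan(energies).any():
        raise TorsionTableError("table rows do not cover the full grid")
    return TorsionTable(code, spacing, energies, mask)


def dumps(table: TorsionTable) -> str:
    lines = [f"code {table.code}", f"spacing {table.spacing:g}",
             "phi psi energy masked"]
    nodes = table.nodes
    for i in range(table.n):
        for j in range(table.n):
            lines.append(f"{nodes[i]:g} {nodes[j]:g} "
                         f"{table.energies[i, j]:.4f} "
                         f"{int(table.mask[i, j])}")
    return "\n".join(lines) + "\n"


@functools.lru_cache(maxsize=None)
def load_table(name: str) -> TorsionTable:
    """Load a shipped table by name (general, gly, dha, dhb)."""
    ref = resources.files("lanthimodel.data") / f"rama_{name.lower()}.tbl"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise TorsionTableError(f"no shipped table {name!r}") from None
    return loads(text)


@functools.lru_cache(maxsize=None)
def table_for_residue(code: str, chirality: str = "L") -> TorsionTable:
    """Resolve the table used to score/sample a residue type."""
    if code == "DHA":
        return load_table("dha")
    if code == "DHB":
        return load_table("dhb")
    if code == "GLY":
        return load_table("gly")
    if chirality == "D":
        return load_table("general").mirrored()
    return load_table("general")


def score_torsion(table: TorsionTable, phi, psi):
    return table.score(phi, psi)


def sample_torsion(table: TorsionTable, rng: np.random.Generator,
                   temperature: float = 1.0):
    return table.sample(rng, temperature)
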