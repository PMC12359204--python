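"""Cartesian geometry: conformer construction, torsions, superposition.

Conformers are built in internal coordinates (NeRF chain extension) from
ideal bond lengths and angles, with a reduced atom set per residue:
backbone N, H, CA, HA, C, O plus CB for non-glycine residues, CG for
beta-methyl residues (Dhb, Abu/Thr-derived) and SG for cysteines.  This is
the minimal set needed for thioether ring modeling and for amide/alpha
proton and methyl-pseudoatom NOE groups; sidechains beyond CB/CG are not
modeled.

Residues with an sp2 alpha carbon (Dha, Dhb) get planar 120-degree
geometry at CA and carry no HA; D-residues mirror the CB/HA branch
torsions.  All angles in the public interface are degrees; coordinates
are Angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import LanthipeptideTopology, RingSpec

__all__ = [
    "Conformer",
    "GeometryError",
    "build_conformer",
    "dihedral",
    "bond_angle",
    "place_atom",
    "superpose",
    "SuperposeResult",
    "backbone_rmsd",
    "ring_atom_selection",
    "ring_rmsd",
    "measure_phi_psi",
]


class GeometryError(ValueError):
    """Raised for missing atoms, degenerate selections and build errors."""


# ideal internal coordinates (Angstrom / degrees), Engh-Huber-class values
IDEAL = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("N", "H"): 1.010,
    ("CA", "CB"): 1.530,
    ("CA", "CB_sp2"): 1.500,   # C=C for dehydro residues
    ("CA", "HA"): 1.090,
    ("CB", "CG"): 1.521,
    ("CB", "SG"): 1.810,
    "C-N-CA": 121.7,
    "N-CA-C": 111.2,
    "N-CA-C_sp2": 118.0,
    "CA-C-N": 116.6,
    "CA-C-O": 120.5,
    "C-N-H": 119.0,
    "N-CA-CB": 110.5,
    "N-CA-CB_sp2": 122.0,
    "CA-CB-CG": 111.0,
    "CA-CB-CG_sp2": 124.0,
    "CA-CB-SG": 114.0,
    # branch torsions about the N-CA axis, L convention (negated for D)
    "C-N-CA-CB": 122.5,
    "C-N-CA-HA": -118.3,
}

OMEGA = 180.0  # trans peptide bond throughout


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector in geometry computation")
    return v / n


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: return d with |c-d|=bond, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion (degrees)."""
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees."""
    v1 = _unit(np.asarray(p1, float) - np.asarray(p2, float))
    v2 = _unit(np.asarray(p3, float) - np.asarray(p2, float))
    return float(np.rad2deg(np.arccos(np.clip(v1 @ v2, -1.0, 1.0))))


def wrap_angle(x):
    """Wrap degrees into (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# Conformer container


@dataclass
class Conformer:
    """One model: ordered atoms with Cartesian coordinates, tied to a topology.

    ``atoms`` is an ordered list of ``(residue_position, atom_name, element)``;
    ``coords`` the matching ``(n_atoms, 3)`` array in Angstroms.
    """

    topology: LanthipeptideTopology
    atoms: tuple[tuple[int, str, str], ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise GeometryError("coords shape does not match atom list")
        self._index = {(p, n): i for i, (p, n, _e) in enumerate(self.atoms)}

    def copy(self) -> "Conformer":
        return Conformer(self.topology, self.atoms, self.coords.copy())

    def index_of(self, position: int, name: str) -> int:
        try:
            return self._index[(position, name)]
        except KeyError:
            raise GeometryError(
                f"atom {name} of residue {position} not present"
            ) from None

    def has_atom(self, position: int, name: str) -> bool:
        return (position, name) in self._index

    def xyz(self, position: int, name: str) -> np.ndarray:
        return self.coords[self.index_of(position, name)]

    def select(self, names: tuple[str, ...] = ("N", "CA", "C"),
               positions=None) -> np.ndarray:
        """Indices of the named atoms, in chain order."""
        if positions is None:
            positions = range(1, len(self.topology) + 1)
        idx = []
        for p in positions:
            for name in names:
                if (p, name) in self._index:
                    idx.append(self._index[(p, name)])
        return np.array(idx, dtype=int)

    # --- torsion machinery -------------------------------------------------

    def _axis_and_moved(self, kind: str, res: int):
        """Rotation axis (i, j) and the indices rigidly moved by the torsion.

        phi(r): axis N-CA, moves everything after CA of r.
        psi(r): axis CA-C, moves O(r) and all later residues.
        chi(r): axis CA-CB, moves the CG/SG branch only.
        """
        if kind == "phi":
            i, j = self.index_of(res, "N"), self.index_of(res, "CA")
            moved = [k for k, (p, n, _e) in enumerate(self.atoms)
                     if p > res or (p == res and n not in ("N", "H", "CA"))]
        elif kind == "psi":
            i, j = self.index_of(res, "CA"), self.index_of(res, "C")
            moved = [k for k, (p, n, _e) in enumerate(self.atoms)
                     if p > res or (p == res and n == "O")]
        elif kind == "chi":
            i, j = self.index_of(res, "CA"), self.index_of(res, "CB")
            moved = [k for k, (p, n, _e) in enumerate(self.atoms)
                     if p == res and n in ("CG", "SG")]
        else:
            raise GeometryError(f"unknown torsion kind {kind!r}")
        return i, j, np.array(moved, dtype=int)

    def rotate_torsion(self, kind: str, res: int, delta_deg: float) -> None:
        """Rotate the torsion by ``delta_deg`` in place.

        A pure torsion rotation: every bond length and bond angle is
        preserved, only this dihedral (and the rigid placement of the
        downstream atoms) changes.
        """
        i, j, moved = self._axis_and_moved(kind, res)
        if moved.size == 0:
            return
        axis = _unit(self.coords[j] - self.coords[i])
        theta = -np.deg2rad(delta_deg)  # sign matches the dihedral convention
        k = axis
        pts = self.coords[moved] - self.coords[j]
        # Rodrigues rotation, vectorized
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        pts_rot = (pts * cos_t
                   + np.cross(k, pts) * sin_t
                   + np.outer(pts @ k, k) * (1.0 - cos_t))
        self.coords[moved] = pts_rot + self.coords[j]

    def get_torsion(self, kind: str, res: int) -> float:
        n = len(self.topology)
        if kind == "phi":
            if res <= 1:
                raise GeometryError("phi undefined for the first residue")
            return dihedral(self.xyz(res - 1, "C"), self.xyz(res, "N"),
                            self.xyz(res, "CA"), self.xyz(res, "C"))
        if kind == "psi":
            if res < n:
                return dihedral(self.xyz(res, "N"), self.xyz(res, "CA"),
                                self.xyz(res, "C"), self.xyz(res + 1, "N"))
            # last residue: infer from the carbonyl O (built at psi + 180)
            return float(wrap_angle(
                dihedral(self.xyz(res, "N"), self.xyz(res, "CA"),
                         self.xyz(res, "C"), self.xyz(res, "O")) - 180.0))
        if kind == "chi":
            return dihedral(self.xyz(res, "N"), self.xyz(res, "CA"),
                            self.xyz(res, "CB"),
                            self.xyz(res, "SG") if self.has_atom(res, "SG")
                            else self.xyz(res, "CG"))
        raise GeometryError(f"unknown torsion kind {kind!r}")

    def set_torsion(self, kind: str, res: int, value_deg: float) -> None:
        current = self.get_torsion(kind, res)
        self.rotate_torsion(kind, res, value_deg - current)


def measure_phi_psi(conformer: Conformer) -> np.ndarray:
    """(n, 2) array of backbone torsions in degrees; phi(1) is NaN."""
    n = len(conformer.topology)
    out = np.full((n, 2), np.nan)
    for r in range(1, n + 1):
        if r > 1:
            out[r - 1, 0] = conformer.get_torsion("phi", r)
        out[r - 1, 1] = conformer.get_torsion("psi", r)
    return out


# ---------------------------------------------------------------------------
# Builder


def _element(name: str) -> str:
    return "S" if name.startswith("S") else name[0]


def build_conformer(topology: LanthipeptideTopology,
                    phi_psi: np.ndarray) -> Conformer:
    """Build an open-chain conformer from per-residue (phi, psi) torsions.

    Bond lengths and angles take the ideal values; the peptide bond is
    trans.  phi of residue 1 is accepted but has no geometric effect.
    Thioether rings are *not* closed here — see
    :func:`lanthimodel.crosslink.close_ring`.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n = len(topology)
    if phi_psi.shape != (n, 2):
        raise GeometryError(
            f"need ({n}, 2) torsions for {n} residues, got {phi_psi.shape}"
        )

    atoms: list[tuple[int, str, str]] = []
    coords: list[np.ndarray] = []
    pos_of: dict[tuple[int, str], int] = {}

    def add(resnum: int, name: str, xyz: np.ndarray) -> None:
        pos_of[(resnum, name)] = len(atoms)
        atoms.append((resnum, name, _element(name)))
        coords.append(np.asarray(xyz, float))

    def get(resnum: int, name: str) -> np.ndarray:
        return coords[pos_of[(resnum, name)]]

    prev_c = prev_ca = prev_n = None
    for r in range(1, n + 1):
        spec = topology.residue(r)
        sp2 = spec.alpha_sp2
        phi, psi = phi_psi[r - 1]
        if r == 1:
            n_xyz = np.zeros(3)
            ca_xyz = np.array([IDEAL[("N", "CA")], 0.0, 0.0])
            ang = np.deg2rad(IDEAL["N-CA-C_sp2" if sp2 else "N-CA-C"])
            c_xyz = ca_xyz + IDEAL[("CA", "C")] * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_xyz = place_atom(prev_n, prev_ca, prev_c,
                               IDEAL[("C", "N")], IDEAL["CA-C-N"],
                               phi_psi[r - 2, 1])
            ca_xyz = place_atom(prev_ca, prev_c, n_xyz,
                                IDEAL[("N", "CA")], IDEAL["C-N-CA"], OMEGA)
            c_xyz = place_atom(prev_c, n_xyz, ca_xyz,
                               IDEAL[("CA", "C")],
                               IDEAL["N-CA-C_sp2" if sp2 else "N-CA-C"],
                               phi)
        add(r, "N", n_xyz)
        # amide H in the peptide plane, trans to the carbonyl O
        if r > 1 and spec.code not in ("PRO", "DPR"):
            h_xyz = place_atom(get(r - 1, "O"), prev_c, n_xyz,
                               IDEAL[("N", "H")], IDEAL["C-N-H"], 180.0)
            add(r, "H", h_xyz)
        add(r, "CA", ca_xyz)

        mirror = -1.0 if spec.chirality == "D" else 1.0
        if spec.code == "GLY":
            for name, tor in (("HA2", IDEAL["C-N-CA-CB"]),
                              ("HA3", IDEAL["C-N-CA-HA"])):
                add(r, name, place_atom(c_xyz, n_xyz, ca_xyz,
                                        IDEAL[("CA", "HA")],
                                        IDEAL["N-CA-CB"], tor))
        else:
            cb_key = ("CA", "CB_sp2") if sp2 else ("CA", "CB")
            cb_ang = IDEAL["N-CA-CB_sp2"] if sp2 else IDEAL["N-CA-CB"]
            cb_tor = 180.0 if sp2 else mirror * IDEAL["C-N-CA-CB"]
            cb_xyz = place_atom(c_xyz, n_xyz, ca_xyz,
                                IDEAL[cb_key], cb_ang, cb_tor)
            add(r, "CB", cb_xyz)
            if not sp2:
                add(r, "HA", place_atom(c_xyz, n_xyz, ca_xyz,
                                        IDEAL[("CA", "HA")],
                                        IDEAL["N-CA-CB"],
                                        mirror * IDEAL["C-N-CA-HA"]))
            if spec.has_beta_methyl:
                if sp2:  # Dhb: Z isomer, methyl cis to N across CA=CB
                    cg_xyz = place_atom(n_xyz, ca_xyz, cb_xyz,
                                        IDEAL[("CB", "CG")],
                                        IDEAL["CA-CB-CG_sp2"], 0.0)
                else:
                    cg_xyz = place_atom(n_xyz, ca_xyz, cb_xyz,
                                        IDEAL[("CB", "CG")],
                                        IDEAL["CA-CB-CG"], 180.0)
                add(r, "CG", cg_xyz)
            if spec.code in ("CYS", "DCY"):
                add(r, "SG", place_atom(n_xyz, ca_xyz, cb_xyz,
                                        IDEAL[("CB", "SG")],
                                        IDEAL["CA-CB-SG"], -60.0))
        add(r, "C", c_xyz)
        add(r, "O", place_atom(n_xyz, ca_xyz, c_xyz,
                               IDEAL[("C", "O")], IDEAL["CA-C-O"],
                               psi + 180.0))
        prev_n, prev_ca, prev_c = n_xyz, ca_xyz, c_xyz

    return Conformer(topology, tuple(atoms), np.array(coords))


# ---------------------------------------------------------------------------
# Superposition (Kabsch)


@dataclass(frozen=True)
class SuperposeResult:
    rotation: np.ndarray     # (3, 3), proper (det +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperposeResult:
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 matched atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = (mobile - mc) @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    translation = rc - rot @ mc
    return SuperposeResult(rot, translation, rmsd)


def superpose(mobile: Conformer, reference: Conformer,
              selection: tuple[str, ...] = ("N", "CA", "C"),
              positions=None) -> SuperposeResult:
    """Least-squares rigid superposition (proper rotation only).

    ``selection`` names the atoms used (default backbone N, CA, C);
    ``positions`` optionally restricts to a residue subset.
    """
    idx_m = mobile.select(selection, positions)
    idx_r = reference.select(selection, positions)
    if idx_m.size != idx_r.size:
        raise GeometryError("selections give different atom counts")
    return _kabsch(mobile.coords[idx_m], reference.coords[idx_r])


def backbone_rmsd(a: Conformer, b: Conformer, positions=None) -> float:
    return superpose(a, b, ("N", "CA", "C"), positions).rmsd


def ring_atom_selection(conformer: Conformer, ring: RingSpec):
    """Atom indices defining a ring for RMSD purposes: backbone N/CA/C of
    the ring span plus CB of donor and acceptor and the acceptor SG."""
    lo, hi = ring.span
    idx = list(conformer.select(("N", "CA", "C"), range(lo, hi + 1)))
    for pos, name in ((ring.donor_pos, "CB"), (ring.acceptor_pos, "CB"),
                      (ring.acceptor_pos, "SG")):
        idx.append(conformer.index_of(pos, name))
    return np.array(idx, dtype=int)


def ring_rmsd(a: Conformer, b: Conformer, ring: RingSpec) -> float:
    """RMSD over the ring atom set after superposing on that same set."""
    ia = ring_atom_selection(a, ring)
    ib = ring_atom_selection(b, ring)
    return _kabsch(a.coords[ia], b.coords[ib]).rmsd
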