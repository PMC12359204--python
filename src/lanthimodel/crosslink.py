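"""Thioether crosslink geometry: targets, deviation reports, ring closure.

A lanthionine ring is closed by a C-S bond between the donor CB and the
acceptor cysteine SG.  The geometry of the closed ring is described by the
new bond length, the two flanking bond angles and three dihedrals across
the bond region; methyllanthionine adds an improper dihedral and two bond
angles involving the donor beta-methyl that maintain the stereochemistry
at the bridge carbon.

Defaults are standard thioether values (C-S 1.81 A, C-C-S 109.5 deg,
C-S-C 98 deg); they are configurable data, not ground truth, and may be
overridden with force-field-derived numbers.

Ring closure is cyclic coordinate descent (CCD) over the backbone torsions
inside the ring span (plus the acceptor chi1): each torsion in turn is set
to the angle minimizing the bond + flanking-angle objective, preserving
every bond length and bond angle by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import (
    Conformer,
    GeometryError,
    bond_angle,
    dihedral,
    place_atom,
    wrap_angle,
)
from .topology import RingSpec

__all__ = [
    "CrosslinkGeometry",
    "TermReport",
    "DeviationReport",
    "RingClosureResult",
    "measure_crosslink",
    "close_ring",
    "close_all_rings",
    "build_ideal_ring_fragment",
]


@dataclass(frozen=True)
class CrosslinkGeometry:
    """Target internal coordinates of the thioether bridge.

    ``angle_targets`` flank the C-S bond: (CA_d-CB_d-SG, CB_d-SG-CB_a).
    ``dihedral_targets`` run across the bond region:
    (N_d-CA_d-CB_d-SG, CA_d-CB_d-SG-CB_a, CB_d-SG-CB_a-CA_a).
    The improper dihedral (CA_d, CG_d, CB_d, SG) encodes the configuration
    at the donor bridge carbon and applies to methyllanthionine only, as do
    the methyl angles (CA_d-CB_d-CG_d, CG_d-CB_d-SG).
    """

    cs_bond_length: float = 1.81
    angle_targets: tuple[float, float] = (109.5, 98.0)
    dihedral_targets: tuple[float, float, float] = (180.0, -80.0, -60.0)
    improper_target: float = -35.0
    methyl_angle_targets: tuple[float, float] = (111.0, 109.5)
    bond_weight: float = 100.0      # per A^2
    angle_weight: float = 0.02      # per deg^2
    dihedral_weight: float = 0.002  # per deg^2
    improper_weight: float = 0.01   # per deg^2
    bond_tol: float = 0.02          # A
    angle_tol: float = 5.0          # deg

    def __post_init__(self) -> None:
        if self.cs_bond_length <= 0:
            raise ValueError("cs_bond_length must be positive")
        for a in self.angle_targets + self.methyl_angle_targets:
            if not 0.0 < a < 180.0:
                raise ValueError(f"angle target {a} outside (0, 180)")
        if self.bond_tol <= 0 or self.angle_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class TermReport:
    name: str
    target: float
    observed: float
    deviation: float  # >= 0; angles wrapped to the shortest arc
    weight: float

    @property
    def penalty(self) -> float:
        return self.weight * self.deviation ** 2


@dataclass(frozen=True)
class DeviationReport:
    terms: tuple[TermReport, ...]

    @property
    def total(self) -> float:
        return float(sum(t.penalty for t in self.terms))

    def term(self, name: str) -> TermReport:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _ring_key_atoms(conformer: Conformer, ring: RingSpec):
    d, a = ring.donor_pos, ring.acceptor_pos
    needed = [(d, "N"), (d, "CA"), (d, "CB"),
              (a, "CA"), (a, "CB"), (a, "SG")]
    for pos, name in needed:
        if not conformer.has_atom(pos, name):
            raise GeometryError(
                f"ring {d}-{a}: atom {name} of residue {pos} missing"
            )
    return {name + ("_d" if pos == d else "_a"): conformer.xyz(pos, name)
            for pos, name in needed}


def measure_crosslink(conformer: Conformer, ring: RingSpec,
                      geometry: CrosslinkGeometry | None = None
                      ) -> DeviationReport:
    """Deviations of every crosslink term from its target."""
    g = geometry or CrosslinkGeometry()
    k = _ring_key_atoms(conformer, ring)
    terms: list[TermReport] = []

    def add(name, target, observed, weight, wrap=False):
        dev = abs(float(wrap_angle(observed - target)) if wrap
                  else observed - target)
        terms.append(TermReport(name, target, float(observed), dev, weight))

    add("cs_bond", g.cs_bond_length,
        np.linalg.norm(k["CB_d"] - k["SG_a"]), g.bond_weight)
    add("angle_ca_cb_sg", g.angle_targets[0],
        bond_angle(k["CA_d"], k["CB_d"], k["SG_a"]), g.angle_weight)
    add("angle_cb_sg_cb", g.angle_targets[1],
        bond_angle(k["CB_d"], k["SG_a"], k["CB_a"]), g.angle_weight)
    add("dihedral_n_ca_cb_sg", g.dihedral_targets[0],
        dihedral(k["N_d"], k["CA_d"], k["CB_d"], k["SG_a"]),
        g.dihedral_weight, wrap=True)
    add("dihedral_ca_cb_sg_cb", g.dihedral_targets[1],
        dihedral(k["CA_d"], k["CB_d"], k["SG_a"], k["CB_a"]),
        g.dihedral_weight, wrap=True)
    add("dihedral_cb_sg_cb_ca", g.dihedral_targets[2],
        dihedral(k["CB_d"], k["SG_a"], k["CB_a"], k["CA_a"]),
        g.dihedral_weight, wrap=True)

    if ring.ring_type == "methyllanthionine":
        dpos = ring.donor_pos
        if not conformer.has_atom(dpos, "CG"):
            raise GeometryError(
                f"methyllanthionine donor {dpos}: beta-methyl CG missing"
            )
        cg = conformer.xyz(dpos, "CG")
        add("improper_methyl", g.improper_target,
            dihedral(k["CA_d"], cg, k["CB_d"], k["SG_a"]),
            g.improper_weight, wrap=True)
        add("angle_ca_cb_cg", g.methyl_angle_targets[0],
            bond_angle(k["CA_d"], k["CB_d"], cg), g.angle_weight)
        add("angle_cg_cb_sg", g.methyl_angle_targets[1],
            bond_angle(cg, k["CB_d"], k["SG_a"]), g.angle_weight)

    return DeviationReport(tuple(terms))


# ---------------------------------------------------------------------------
# Ring closure (CCD)


@dataclass
class RingClosureResult:
    """Outcome of a closure attempt; ``conformer`` always carries the best
    geometry reached, converged or not, so callers can retry or inspect."""

    conformer: Conformer
    converged: bool
    gap: float            # |C-S distance - target| in A
    max_angle_dev: float  # worst flanking-angle deviation in deg
    n_sweeps: int


def _ring_rotatables(conformer: Conformer, ring: RingSpec):
    lo, hi = ring.span
    if hi - lo < 2:
        raise GeometryError(
            f"ring {ring.donor_pos}-{ring.acceptor_pos}: no rotatable "
            "backbone torsion between donor and acceptor"
        )
    rotatables: list[tuple[str, int]] = [("psi", lo)]
    for r in range(lo + 1, hi):
        rotatables.append(("phi", r))
        rotatables.append(("psi", r))
    rotatables.append(("phi", hi))
    if conformer.has_atom(ring.acceptor_pos, "SG"):
        rotatables.append(("chi", ring.acceptor_pos))
    return rotatables


def _closure_devs(conformer: Conformer, ring: RingSpec,
                  g: CrosslinkGeometry):
    k = _ring_key_atoms(conformer, ring)
    gap = abs(float(np.linalg.norm(k["CB_d"] - k["SG_a"])) - g.cs_bond_length)
    a1 = abs(bond_angle(k["CA_d"], k["CB_d"], k["SG_a"]) - g.angle_targets[0])
    a2 = abs(bond_angle(k["CB_d"], k["SG_a"], k["CB_a"]) - g.angle_targets[1])
    return gap, max(a1, a2)


def close_ring(conformer: Conformer, ring: RingSpec,
               geometry: CrosslinkGeometry | None = None,
               max_iter: int = 60, tol: float = 0.02) -> RingClosureResult:
    """Close one thioether ring by cyclic coordinate descent.

    Only torsions within the ring span (donor psi through acceptor phi,
    plus the acceptor chi1) are altered; bond lengths and bond angles are
    untouched.  Success means the C-S gap is below ``tol`` and both
    flanking angles are within the geometry's angle tolerance.  The input
    conformer is not modified.
    """
    g = geometry or CrosslinkGeometry()
    conf = conformer.copy()
    rotatables = _ring_rotatables(conf, ring)

    d, a = ring.donor_pos, ring.acceptor_pos
    key = [(d, "CA"), (d, "CB"), (a, "CA"), (a, "CB"), (a, "SG")]
    key_idx = np.array([conf.index_of(*ka) for ka in key])

    # normalized closure objective over the 5 key points, batched over
    # leading axes: points[..., 5, 3]
    s_d, s_a = g.bond_tol, g.angle_tol

    def _angles(v1, v2):
        c = np.sum(v1 * v2, axis=-1) / (
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
        return np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))

    def objective(points: np.ndarray) -> np.ndarray:
        ca_d, cb_d, cb_a, sg = (points[..., 0, :], points[..., 1, :],
                                points[..., 3, :], points[..., 4, :])
        dd = np.linalg.norm(cb_d - sg, axis=-1) - g.cs_bond_length
        da1 = _angles(ca_d - cb_d, sg - cb_d) - g.angle_targets[0]
        da2 = _angles(cb_d - sg, cb_a - sg) - g.angle_targets[1]
        return (dd / s_d) ** 2 + (da1 / s_a) ** 2 + (da2 / s_a) ** 2

    gap, ang = _closure_devs(conf, ring, g)
    if gap < tol and ang < g.angle_tol:
        return RingClosureResult(conf, True, gap, ang, 0)

    coarse = np.linspace(-180.0, 180.0, 73)[:-1]
    for sweep in range(1, max_iter + 1):
        improved = False
        for kind, res in rotatables:
            i, j, moved = conf._axis_and_moved(kind, res)
            moved_set = set(moved.tolist())
            which = np.array([ki in moved_set for ki in key_idx])
            if not which.any():
                continue
            pivot = conf.coords[j]
            axis = conf.coords[j] - conf.coords[i]
            axis = axis / np.linalg.norm(axis)
            pts = conf.coords[key_idx]
            rel = pts[which] - pivot

            def _rotated(theta_rad):
                # theta_rad: (...,) -> points (..., 5, 3)
                th = np.atleast_1d(np.asarray(theta_rad, float))
                cos_t = np.cos(th)[:, None, None]
                sin_t = np.sin(th)[:, None, None]
                rot = (rel[None] * cos_t
                       + np.cross(axis, rel)[None] * sin_t
                       + ((rel @ axis)[None, :, None] * axis[None, None, :])
                       * (1 - cos_t))
                p = np.broadcast_to(pts, (th.size, *pts.shape)).copy()
                p[:, which] = rot + pivot
                return p

            def eval_theta(theta_deg: float) -> float:
                return float(objective(_rotated(np.deg2rad(theta_deg)))[0])

            base = eval_theta(0.0)
            vals = objective(_rotated(np.deg2rad(coarse)))
            best_i = int(np.argmin(vals))
            res_opt = minimize_scalar(
                eval_theta,
                bounds=(coarse[best_i] - 5.0, coarse[best_i] + 5.0),
                method="bounded",
                options={"xatol": 1e-4},
            )
            best_theta, best_val = float(res_opt.x), float(res_opt.fun)
            if best_val < base - 1e-12:
                conf.rotate_torsion(kind, res, best_theta)
                improved = True
        gap, ang = _closure_devs(conf, ring, g)
        if gap < tol and ang < g.angle_tol:
            return RingClosureResult(conf, True, gap, ang, sweep)
        if not improved:
            break

    # CCD is coordinate-wise greedy and can stall with the bond formed but
    # the flanking angles strained; polish jointly over all ring torsions.
    from scipy.optimize import minimize

    def full_obj(deltas: np.ndarray) -> float:
        c2 = conf.copy()
        for (kind, res), dlt in zip(rotatables, deltas):
            if dlt != 0.0:
                c2.rotate_torsion(kind, res, dlt)
        return float(objective(c2.coords[key_idx][None])[0])

    opt = minimize(full_obj, np.zeros(len(rotatables)), method="Powell",
                   options={"maxiter": 40, "xtol": 1e-3, "ftol": 1e-6})
    if opt.fun < objective(conf.coords[key_idx][None])[0]:
        for (kind, res), dlt in zip(rotatables, opt.x):
            if dlt != 0.0:
                conf.rotate_torsion(kind, res, dlt)
    gap, ang = _closure_devs(conf, ring, g)
    converged = gap < tol and ang < g.angle_tol
    return RingClosureResult(conf, converged, gap, ang, sweep)


def close_all_rings(conformer: Conformer,
                    rings: tuple[RingSpec, ...],
                    geometry: CrosslinkGeometry | None = None,
                    max_iter: int = 60, tol: float = 0.02):
    """Close rings in the given order; returns (conformer, all_converged)."""
    conf = conformer
    ok = True
    for ring in rings:
        result = close_ring(conf, ring, geometry, max_iter, tol)
        conf = result.conformer
        ok = ok and result.converged
    return conf, ok


# ---------------------------------------------------------------------------
# Ideal fragment (used by tests and fixture generators)


def build_ideal_ring_fragment(geometry: CrosslinkGeometry | None = None
                              ) -> Conformer:
    """A minimal two-residue lanthionine fragment hitting every lanthionine
    crosslink target exactly; measure_crosslink on it reports zero total."""
    from .topology import parse_topology

    g = geometry or CrosslinkGeometry()
    topo = parse_topology("seq AC\nring 1-2 lan\n")
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([1.458, 0.0, 0.0])
    dummy = np.array([0.0, 1.0, 0.0])
    cb1 = place_atom(dummy, n1, ca1, 1.530, 110.5, 37.0)
    sg = place_atom(n1, ca1, cb1, g.cs_bond_length, g.angle_targets[0],
                    g.dihedral_targets[0])
    cb2 = place_atom(ca1, cb1, sg, 1.810, g.angle_targets[1],
                     g.dihedral_targets[1])
    ca2 = place_atom(cb1, sg, cb2, 1.530, 114.0, g.dihedral_targets[2])
    atoms = ((1, "N", "N"), (1, "CA", "C"), (1, "CB", "C"),
             (2, "CA", "C"), (2, "CB", "C"), (2, "SG", "S"))
    coords = np.array([n1, ca1, cb1, ca2, cb2, sg])
    return Conformer(topo, atoms, coords)
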