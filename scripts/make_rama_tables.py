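"""Regenerate the shipped backbone-torsion tables.

The tables are coarse, qualitative analytic surfaces:

* ``general`` — canonical L-amino acids: alpha, beta and polyproline-II
  basins plus a weak left-handed alpha basin.
* ``gly`` — glycine: the general surface symmetrized under
  (phi, psi) -> (-phi, -psi), reflecting the missing CB.
* ``dha`` — dehydroalanine: sp2 alpha carbon, C2-symmetric surface with
  broad planar-conjugation basins.
* ``dhb`` — dehydrobutyrine: the Dha surface plus a steric penalty where
  the Z-configured gamma methyl approaches the backbone, so its allowed
  region is a strict subset of Dha's.

Cells with energy above MASK_CUTOFF are marked disallowed.  Energies are
in arbitrary kcal/mol-like units, meaningful up to an additive constant;
substitute quantum-chemistry-derived files in the same format for
production work on real peptides.

Run from the repository root:  python scripts/make_rama_tables.py
"""

from pathlib import Path

import numpy as np

SPACING = 15.0
MASK_CUTOFF = 6.0
E_CAP = 9.9

OUT = Path(__file__).resolve().parent.parent / "src" / "lanthimodel" / "data"


def wrap(x):
    return (x + 180.0) % 360.0 - 180.0


def basin(phi, psi, c_phi, c_psi, s_phi, s_psi, w):
    """Periodic 2D Gaussian population component."""
    d_phi = wrap(phi - c_phi) / s_phi
    d_psi = wrap(psi - c_psi) / s_psi
    return w * np.exp(-0.5 * (d_phi ** 2 + d_psi ** 2))


def to_energy(pop):
    e = -np.log(pop + 1e-6)
    e -= e.min()
    return np.minimum(e, E_CAP)


def grids():
    nodes = -180.0 + SPACING * np.arange(int(360 / SPACING))
    return np.meshgrid(nodes, nodes, indexing="ij")


def general_surface():
    phi, psi = grids()
    pop = (basin(phi, psi, -63, -43, 25, 25, 1.0)       # alpha
           + basin(phi, psi, -120, 130, 35, 30, 0.9)    # beta
           + basin(phi, psi, -65, 145, 25, 30, 0.8)     # ppII
           + basin(phi, psi, 55, 40, 15, 15, 0.25))     # alpha-L
    return to_energy(pop)


def gly_surface():
    phi, psi = grids()
    pop = (basin(phi, psi, -90, 0, 30, 35, 1.0)
           + basin(phi, psi, 90, 0, 30, 35, 1.0)
           + basin(phi, psi, -180, 180, 45, 45, 0.6)
           + basin(phi, psi, -80, 150, 30, 30, 0.5)
           + basin(phi, psi, 80, -150, 30, 30, 0.5))
    return to_energy(pop)


def dha_surface():
    phi, psi = grids()
    half = (basin(phi, psi, -55, -30, 30, 28, 1.0)
            + basin(phi, psi, -150, 165, 35, 30, 0.7))
    sym = half + (basin(phi, psi, 55, 30, 30, 28, 1.0)
                  + basin(phi, psi, 150, -165, 35, 30, 0.7))
    return to_energy(sym)


def dhb_surface():
    phi, psi = grids()
    e = dha_surface()
    # Z-methyl / backbone clash: penalize the inner part of each basin
    clash = (6.0 * basin(phi, psi, -55, 30, 35, 35, 1.0)
             + 6.0 * basin(phi, psi, 55, -30, 35, 35, 1.0)
             + 4.0 * basin(phi, psi, -100, -60, 30, 30, 1.0)
             + 4.0 * basin(phi, psi, 100, 60, 30, 30, 1.0))
    return np.minimum(e + clash, E_CAP)


def write(name, energies):
    n = energies.shape[0]
    nodes = -180.0 + SPACING * np.arange(n)
    mask = energies > MASK_CUTOFF
    lines = [f"code {name.upper()}", f"spacing {SPACING:g}",
             "phi psi energy masked"]
    for i in range(n):
        for j in range(n):
            lines.append(f"{nodes[i]:g} {nodes[j]:g} "
                         f"{energies[i, j]:.4f} {int(mask[i, j])}")
    path = OUT / f"rama_{name}.tbl"
    path.write_text("\n".join(lines) + "\n")
    print(f"{path}: {n * n} cells, {int(mask.sum())} masked")
    return mask


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    write("general", general_surface())
    write("gly", gly_surface())
    mask_dha = write("dha", dha_surface())
    mask_dhb = write("dhb", dhb_surface())
    allowed_dha = ~mask_dha
    allowed_dhb = ~mask_dhb
    assert np.all(allowed_dhb <= allowed_dha), "Dhb allowed must be subset"
    assert allowed_dhb.sum() < allowed_dha.sum(), "subset must be strict"
    print("Dhb allowed strictly within Dha allowed: OK")


if __name__ == "__main__":
    main()
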