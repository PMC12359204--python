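"""Multi-model PDB read/write for conformer ensembles (via gemmi).

Models are numbered from 1 in pool order; the thioether bond of each ring
is emitted as a LINK record between the donor CB and acceptor SG.
Noncanonical residues keep their three-letter codes (DHA, DHB, ABU, ...);
the acceptor stays a standard CYS.  An optional provenance header is
written as REMARK 99 lines.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .geometry import Conformer, GeometryError
from .topology import LanthipeptideTopology

__all__ = ["ensemble_to_pdb", "write_ensemble", "read_ensemble"]


def ensemble_to_pdb(pool, remarks: list[str] | None = None) -> str:
    """Serialize conformers (sharing one topology) to multi-model PDB."""
    pool = list(pool)
    if not pool:
        raise GeometryError("empty pool")
    topology = pool[0].topology
    st = gemmi.Structure()
    st.name = "lanthimodel ensemble"
    for num, conf in enumerate(pool, start=1):
        if conf.topology.sequence != topology.sequence:
            raise GeometryError("pool conformers have differing topologies")
        model = gemmi.Model(num)
        chain = gemmi.Chain("A")
        current_res: gemmi.Residue | None = None
        current_pos = None
        for (pos, name, element), xyz in zip(conf.atoms, conf.coords):
            if current_res is None or pos != current_pos:
                if current_res is not None:
                    chain.add_residue(current_res)
                current_res = gemmi.Residue()
                current_res.name = topology.residue(pos).code
                current_res.seqid = gemmi.SeqId(pos, " ")
                current_pos = pos
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*xyz)
            current_res.add_atom(atom)
        if current_res is not None:
            chain.add_residue(current_res)
        model.add_chain(chain)
        st.add_model(model)
    for i, ring in enumerate(topology.rings):
        con = gemmi.Connection()
        con.name = f"lanthi{i + 1}"
        con.type = gemmi.ConnectionType.Covale
        con.partner1 = gemmi.AtomAddress(
            "A", gemmi.SeqId(ring.donor_pos, " "),
            topology.residue(ring.donor_pos).code, "CB", "\0")
        con.partner2 = gemmi.AtomAddress(
            "A", gemmi.SeqId(ring.acceptor_pos, " "),
            topology.residue(ring.acceptor_pos).code, "SG", "\0")
        st.connections.append(con)
    st.setup_entities()
    text = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK  99 {r}\n" for r in remarks)
        text = header + text
    return text


def write_ensemble(pool, path, remarks: list[str] | None = None) -> None:
    Path(path).write_text(ensemble_to_pdb(pool, remarks))


def read_ensemble(source, topology: LanthipeptideTopology):
    """Read a multi-model PDB into conformers tied to ``topology``.

    ``source`` is a path or a PDB string.  Atom records are matched by
    residue number and atom name; extra atoms not in the reduced
    representation are kept as-is on the conformer.
    """
    text = source if "\n" in str(source) else Path(source).read_text()
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise GeometryError("no models in PDB input")
    pool = []
    for model in st:
        atoms = []
        coords = []
        for chain in model:
            for residue in chain:
                pos = residue.seqid.num
                if not 1 <= pos <= len(topology):
                    raise GeometryError(
                        f"residue {pos} outside topology of length "
                        f"{len(topology)}"
                    )
                for atom in residue:
                    atoms.append((pos, atom.name, atom.element.name))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        pool.append(Conformer(topology, tuple(atoms), np.array(coords)))
    return pool
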