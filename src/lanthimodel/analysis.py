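"""Ensemble reports: per-member RMSD, per-ring RMSD, torsion variability.

The reference conformer follows the field's two conventions: model 1 for
ensembles taken from an external multi-model PDB, the lowest-scoring
member for generated ensembles.  Per-residue flexibility is summarized by
the circular variance of phi and psi across the ensemble (0 = rigid,
1 = uniform).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import GeometryError, backbone_rmsd, measure_phi_psi, ring_rmsd

__all__ = ["analyze_ensemble", "circular_variance"]


def circular_variance(angles_deg: np.ndarray) -> float:
    """1 - |mean resultant| of angles in degrees; NaN-tolerant."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    return float(1.0 - np.abs(np.exp(1j * a).mean()))


def analyze_ensemble(ensemble, reference: str = "lowest_score",
                     scores=None):
    """Per-member and per-residue reports for an ensemble.

    Parameters
    ----------
    ensemble : sequence of Conformer (>= 2)
    reference : {"lowest_score", "first"}
        ``"lowest_score"`` requires ``scores`` (one value per member) and
        takes the argmin; ``"first"`` takes model 1 (the convention for
        deposited NMR ensembles).
    scores : sequence of float, optional

    Returns
    -------
    (members, residues) : pair of DataFrames
        ``members``: one row per member with backbone RMSD to the
        reference and per-ring RMSDs.  ``residues``: per-residue circular
        variance of phi and psi across the ensemble.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise GeometryError("ensemble analysis needs at least 2 members")
    if reference == "first":
        ref_idx = 0
    elif reference == "lowest_score":
        if scores is None:
            raise GeometryError(
                "reference='lowest_score' needs per-member scores"
            )
        scores = list(scores)
        if len(scores) != len(ensemble):
            raise GeometryError("scores length does not match ensemble")
        ref_idx = int(np.argmin(scores))
    else:
        raise GeometryError(f"unknown reference policy {reference!r}")

    topology = ensemble[0].topology
    ref = ensemble[ref_idx]
    rows = []
    for i, conf in enumerate(ensemble):
        row = {
            "model": i + 1,
            "is_reference": i == ref_idx,
            "backbone_rmsd": backbone_rmsd(conf, ref),
        }
        if scores is not None:
            row["score"] = scores[i]
        for k, ring in enumerate(topology.rings, start=1):
            row[f"ring{k}_rmsd"] = ring_rmsd(conf, ref, ring)
        rows.append(row)
    members = pd.DataFrame(rows)

    pp = np.stack([measure_phi_psi(c) for c in ensemble])  # (m, n, 2)
    residues = pd.DataFrame({
        "residue": np.arange(1, len(topology) + 1),
        "code": [r.code for r in topology.residues],
        "phi_circ_var": [circular_variance(pp[:, r, 0])
                         for r in range(len(topology))],
        "psi_circ_var": [circular_variance(pp[:, r, 1])
                         for r in range(len(topology))],
    })
    return members, residues
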