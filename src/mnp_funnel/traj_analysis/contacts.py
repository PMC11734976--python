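"""Residue–ligand contact timelines and occupancy percentages.

A residue is "in contact" in a frame when any of its heavy atoms lies
within the cutoff of any ligand heavy atom (4.5 Å default).  The
occupancy percentage of a residue is 100 × the fraction of frames in
contact.  An ionic channel is available separately: charged-group
centroids within an ionic cutoff (5.0 Å default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Trajectory, Selection, resolve_selection

__all__ = ["ContactTimeline", "contact_timeline", "ionic_contact_series"]


@dataclass
class ContactTimeline:
    """Residues × frames boolean contact matrix with occupancies."""

    resids: np.ndarray
    matrix: np.ndarray  # (n_residues, n_frames) bool
    percentages: pd.Series  # index resid, value in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.resids, name="resid"),
            columns=[f"frame{t}" for t in range(self.matrix.shape[1])],
        )


def contact_timeline(
    traj: Trajectory,
    ligand_selection,
    protein_resids=None,
    d_cutoff: float = 4.5,
    heavy_only: bool = True,
) -> ContactTimeline:
    """Heavy-atom distance contacts of each protein residue with the ligand."""
    lig_idx = resolve_selection(traj, ligand_selection)
    elements = traj.atoms["element"].str.upper().to_numpy()
    heavy = elements != "H" if heavy_only else np.ones(traj.n_atoms, bool)
    lig_idx = lig_idx[heavy[lig_idx]]
    if lig_idx.size == 0:
        raise ValueError("ligand selection has no (heavy) atoms")

    resid_col = traj.atoms["resid"].to_numpy()
    in_ligand = np.zeros(traj.n_atoms, dtype=bool)
    in_ligand[lig_idx] = True
    if protein_resids is None:
        protein_resids = sorted(set(resid_col[~in_ligand]))
    resids = np.asarray(list(protein_resids), dtype=int)

    res_atoms = {
        r: np.flatnonzero((resid_col == r) & heavy & ~in_ligand)
        for r in resids
    }
    matrix = np.zeros((len(resids), traj.n_frames), dtype=bool)
    for t in range(traj.n_frames):
        tree = cKDTree(traj.coords[t, lig_idx])
        for k, r in enumerate(resids):
            idx = res_atoms[r]
            if idx.size == 0:
                continue
            dist, _ = tree.query(traj.coords[t, idx], k=1)
            matrix[k, t] = bool((dist <= d_cutoff).any())
    percentages = pd.Series(
        100.0 * matrix.mean(axis=1), index=pd.Index(resids, name="resid")
    )
    return ContactTimeline(resids=resids, matrix=matrix, percentages=percentages)


def ionic_contact_series(
    traj: Trajectory,
    cationic_selection,
    anionic_selection,
    d_cutoff: float = 5.0,
) -> np.ndarray:
    """Per-frame boolean: charged-group centroids within the ionic cutoff."""
    cat = resolve_selection(traj, cationic_selection)
    ani = resolve_selection(traj, anionic_selection)
    cat_c = traj.coords[:, cat, :].mean(axis=1)
    ani_c = traj.coords[:, ani, :].mean(axis=1)
    return np.linalg.norm(cat_c - ani_c, axis=1) <= d_cutoff
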