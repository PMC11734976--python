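"""Synthetic MD trajectories with known per-atom variance.

Frames are drawn from a harmonic-fluctuation model: each coordinate of
atom i fluctuates independently as Normal(0, σ_i²) about a reference
structure, optionally composed with a per-frame rigid rotation and
translation.  The analytic consequences make every trajectory metric
testable: the expected RMSF of atom i is σ_i·√3, rigid motion must be
invisible after superposition, and σ = 0 reproduces the reference in
every frame.

The toy receptor–ligand system emulates the geometry the real pipeline
analyzes — a Cα-trace protein with the CDK4/6 active-site residue
numbering plus a small heteroatom ligand parked near a chosen residue —
but none of the force-field realism; it exists so contact, H-bond and
RMSF reporting have realistic metadata to chew on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..traj_analysis.core import (
    Trajectory,
    element_mass,
    element_radius,
)

__all__ = [
    "HarmonicTrajModel",
    "gen_trajectory",
    "helix_backbone",
    "toy_complex",
    "random_rotation",
]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass
class HarmonicTrajModel:
    """Generative model for one synthetic trajectory.

    ``per_atom_sd`` (Å) is the isotropic per-coordinate fluctuation of
    each atom (scalar = shared by all atoms).  ``rigid_motion`` is
    ``None`` (no global motion), ``"random"`` (an independent random
    rotation+translation per frame), or an explicit sequence of
    ``(rotation, translation)`` pairs, one per frame.
    """

    reference: Trajectory  # single-frame trajectory: the mean structure
    per_atom_sd: float | Sequence[float] = 0.0
    n_frames: int = 100
    rigid_motion: str | Sequence[tuple[np.ndarray, np.ndarray]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference.n_frames != 1:
            raise ValueError("reference must hold exactly one frame")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        n = self.reference.n_atoms
        if np.isscalar(self.per_atom_sd):
            self.per_atom_sd = np.full(n, float(self.per_atom_sd))
        else:
            self.per_atom_sd = np.asarray(self.per_atom_sd, dtype=float)
        if self.per_atom_sd.shape != (n,):
            raise ValueError(
                f"per_atom_sd length {self.per_atom_sd.shape} does not "
                f"match {n} atoms"
            )
        if (self.per_atom_sd < 0).any():
            raise ValueError("per-atom sd must be non-negative")
        if isinstance(self.rigid_motion, (list, tuple)):
            if len(self.rigid_motion) != self.n_frames:
                raise ValueError("need one (rotation, translation) per frame")
            for rot, _ in self.rigid_motion:
                rot = np.asarray(rot)
                if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8) or not (
                    np.isclose(np.linalg.det(rot), 1.0, atol=1e-8)
                ):
                    raise ValueError(
                        "rigid motions must be proper orthonormal rotations"
                    )


def gen_trajectory(model: HarmonicTrajModel) -> Trajectory:
    """Draw one trajectory from the model (deterministic in the seed)."""
    rng = np.random.default_rng(model.seed)
    ref = model.reference.coords[0]
    n = ref.shape[0]
    sd = np.asarray(model.per_atom_sd)
    frames = np.empty((model.n_frames, n, 3))
    for t in range(model.n_frames):
        eps = rng.normal(0.0, 1.0, size=(n, 3)) * sd[:, None]
        x = ref + eps
        if model.rigid_motion == "random":
            rot = random_rotation(rng)
            trans = rng.uniform(-10.0, 10.0, size=3)
            x = x @ rot.T + trans
        elif isinstance(model.rigid_motion, (list, tuple)):
            rot, trans = model.rigid_motion[t]
            x = x @ np.asarray(rot).T + np.asarray(trans)
        frames[t] = x
    return Trajectory(atoms=model.reference.atoms.copy(), coords=frames)


# ---------------------------------------------------------------------------
# toy reference structures

_AA_CYCLE = ("ALA", "GLY", "LEU", "SER", "VAL", "THR", "ILE", "ASP")
# give the CDK4/6 active-site numbering its literature residue names
_NAMED_RESIDUES = {
    19: "ILE",
    24: "TYR",
    41: "ALA",
    99: "GLU",
    103: "GLN",
    104: "ASP",
    162: "ALA",
}


def helix_backbone(
    n_residues: int = 30, start_resid: int = 1, chain: str = "A"
) -> Trajectory:
    """A Cα-trace ideal α-helix (rise 1.5 Å, 100° twist, radius 2.3 Å)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    k = np.arange(n_residues)
    theta = np.radians(100.0) * k
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k]
    )
    resids = start_resid + k
    atoms = pd.DataFrame(
        {
            "name": ["CA"] * n_residues,
            "element": ["C"] * n_residues,
            "resname": [
                _NAMED_RESIDUES.get(int(r), _AA_CYCLE[int(r) % len(_AA_CYCLE)])
                for r in resids
            ],
            "resid": resids.astype(int),
            "chain": [chain] * n_residues,
            "radius": [element_radius("C")] * n_residues,
            "mass": [element_mass("C")] * n_residues,
        }
    )
    return Trajectory(atoms=atoms, coords=coords[None, :, :])


def toy_complex(
    n_residues: int = 170,
    ligand_anchor_resid: int = 104,
    ligand_offset: float = 4.0,
    ligand_resid: int = 900,
) -> Trajectory:
    """A Cα-trace receptor plus a 5-atom heteroatom ligand.

    The protein spans residues 1..n_residues (covering the CDK4/6
    active-site numbering up to ALA162 with the default length); the
    ligand — C3 N O with amine hydrogens omitted — sits
    ``ligand_offset`` Å off the anchor residue's Cα, so short offsets
    guarantee contacts and long ones guarantee their absence.
    """
    protein = helix_backbone(n_residues)
    anchor_idx = int(
        np.flatnonzero(protein.atoms["resid"].to_numpy() == ligand_anchor_resid)[0]
    )
    anchor = protein.coords[0, anchor_idx]
    direction = anchor / np.linalg.norm(anchor + 1e-12) * np.array([1, 1, 0])
    direction = (
        direction / np.linalg.norm(direction)
        if np.linalg.norm(direction) > 0
        else np.array([1.0, 0.0, 0.0])
    )
    base = anchor + direction * ligand_offset
    lig_coords = base + np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.2, 1.3, 0.0],
            [-0.8, 1.2, 0.4],
            [3.6, 1.2, 0.1],
        ]
    )
    lig_elements = ["C", "C", "C", "N", "O"]
    lig_atoms = pd.DataFrame(
        {
            "name": ["C1", "C2", "C3", "N1", "O1"],
            "element": lig_elements,
            "resname": ["LIG"] * 5,
            "resid": [ligand_resid] * 5,
            "chain": ["L"] * 5,
            "radius": [element_radius(e) for e in lig_elements],
            "mass": [element_mass(e) for e in lig_elements],
        }
    )
    atoms = pd.concat([protein.atoms, lig_atoms], ignore_index=True)
    coords = np.concatenate(
        [protein.coords[0], lig_coords], axis=0
    )[None, :, :]
    return Trajectory(atoms=atoms, coords=coords)
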