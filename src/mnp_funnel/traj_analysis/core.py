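"""Trajectory container, atom selections, and element tables.

Coordinates are Ångström throughout; frames share one atom table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BONDI_RADII",
    "ATOMIC_MASSES",
    "Trajectory",
    "Selection",
    "resolve_selection",
    "UnknownElementError",
]

#: Bondi van der Waals radii, Å, keyed by element symbol.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Standard atomic masses, amu.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}


class UnknownElementError(KeyError):
    """An element with no tabulated radius/mass; never silently defaulted."""


def element_radius(element: str) -> float:
    try:
        return BONDI_RADII[element.upper()]
    except KeyError:
        raise UnknownElementError(
            f"no van der Waals radius tabulated for element {element!r}"
        ) from None


def element_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise UnknownElementError(
            f"no atomic mass tabulated for element {element!r}"
        ) from None


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates plus a per-atom metadata table.

    ``atoms`` columns: ``name``, ``element``, ``resname``, ``resid``,
    ``chain``, ``radius`` (Å), ``mass`` (amu).  ``times`` is optional
    per-frame time in ns.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not "
                f"match atom table length {len(self.atoms)}"
            )
        if (self.atoms["radius"] <= 0).any():
            raise ValueError("all van der Waals radii must be positive")
        if (self.atoms["mass"] <= 0).any():
            raise ValueError("all masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> "Trajectory":
        return Trajectory(
            atoms=self.atoms.iloc[indices].reset_index(drop=True),
            coords=self.coords[:, indices, :],
            times=self.times,
        )


@dataclass
class Selection:
    """Declarative atom selection over the atom table.

    All given conditions are ANDed; an empty spec selects every atom.
    """

    names: Sequence[str] | None = None
    elements: Sequence[str] | None = None
    resids: Sequence[int] | None = None
    resnames: Sequence[str] | None = None
    chains: Sequence[str] | None = None
    heavy: bool = False

    def indices(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        if self.names is not None:
            mask &= atoms["name"].isin(list(self.names)).to_numpy()
        if self.elements is not None:
            wanted = {e.upper() for e in self.elements}
            mask &= atoms["element"].str.upper().isin(wanted).to_numpy()
        if self.resids is not None:
            mask &= atoms["resid"].isin(list(self.resids)).to_numpy()
        if self.resnames is not None:
            mask &= atoms["resname"].isin(list(self.resnames)).to_numpy()
        if self.chains is not None:
            mask &= atoms["chain"].isin(list(self.chains)).to_numpy()
        if self.heavy:
            mask &= (atoms["element"].str.upper() != "H").to_numpy()
        return np.flatnonzero(mask)


def resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    """Turn a selection spec / mask / index array into atom indices.

    Accepts ``None`` (all atoms), a :class:`Selection`, a boolean mask,
    or an integer index array.  Raises on an empty result.
    """
    if selection is None:
        idx = np.arange(traj.n_atoms)
    elif isinstance(selection, Selection):
        idx = selection.indices(traj.atoms)
    else:
        arr = np.asarray(selection)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr.astype(int)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    return idx
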