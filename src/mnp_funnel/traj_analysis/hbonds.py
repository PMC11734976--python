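"""Geometric hydrogen-bond counting.

A hydrogen bond is a D–H···A triple with donor–acceptor distance at
most ``d_cutoff`` and D–H···A angle within ``angle_cutoff`` degrees of
linear (i.e. angle ≥ 180° − cutoff).  A heavy-atom-only mode counts
D···A distances alone, for trajectories stripped of hydrogens.
"""

from __future__ import annotations

import numpy as np

from .core import Trajectory, resolve_selection
from .metrics import MetricSeries

__all__ = ["find_polar_hydrogens", "hbond_count_frame", "hbond_count_series"]

_POLAR = ("N", "O")
_DH_BOND_MAX = 1.25  # Å, covalent D-H detection


def find_polar_hydrogens(
    traj: Trajectory, frame: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Detect (donor, hydrogen) pairs and acceptor indices geometrically.

    A hydrogen within covalent range of an N/O in the given frame makes
    that N/O a donor; every N/O is a potential acceptor.
    """
    elements = traj.atoms["element"].str.upper().to_numpy()
    h_idx = np.flatnonzero(elements == "H")
    polar_idx = np.flatnonzero(np.isin(elements, _POLAR))
    coords = traj.coords[frame]
    pairs = []
    for h in h_idx:
        if polar_idx.size == 0:
            break
        d = np.linalg.norm(coords[polar_idx] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= _DH_BOND_MAX:
            pairs.append((int(polar_idx[j]), int(h)))
    return np.asarray(pairs, dtype=int).reshape(-1, 2), polar_idx


def hbond_count_frame(
    coords: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> int:
    """Count hydrogen bonds in one frame.

    ``donors`` is (k, 2) of (D, H) index pairs, or (k,) of donor heavy
    atoms for the distance-only mode.  An acceptor identical to the
    donor (or its hydrogen) never counts.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    heavy_only = donors.ndim == 1
    min_cos = np.cos(np.radians(angle_cutoff))  # cos of allowed deviation
    count = 0
    for donor in donors:
        if heavy_only:
            d_atom, h_atom = int(donor), None
        else:
            d_atom, h_atom = int(donor[0]), int(donor[1])
        for a_atom in acceptors:
            if a_atom == d_atom or a_atom == h_atom:
                continue
            if np.linalg.norm(coords[a_atom] - coords[d_atom]) > d_cutoff:
                continue
            if heavy_only:
                count += 1
                continue
            hd = coords[d_atom] - coords[h_atom]
            ha = coords[a_atom] - coords[h_atom]
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom == 0:
                continue
            # angle(D-H...A) >= 180 - cutoff  <=>  cos(angle) <= -cos(cutoff)
            if float(hd @ ha) / denom <= -min_cos:
                count += 1
    return count


def hbond_count_series(
    traj: Trajectory,
    donors: np.ndarray | None = None,
    acceptors: np.ndarray | None = None,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
    donor_selection=None,
    acceptor_selection=None,
) -> MetricSeries:
    """Hydrogen-bond count per frame.

    Donors/acceptors may be given explicitly (as produced by
    :func:`find_polar_hydrogens`) or restricted by selections after
    automatic detection.  Raises if either side ends up empty.
    """
    if donors is None or acceptors is None:
        auto_donors, auto_acceptors = find_polar_hydrogens(traj)
        if donors is None:
            donors = auto_donors
        if acceptors is None:
            acceptors = auto_acceptors
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donor_selection is not None:
        keep = set(resolve_selection(traj, donor_selection).tolist())
        d_heavy = donors if donors.ndim == 1 else donors[:, 0]
        donors = donors[[int(d) in keep for d in d_heavy]]
    if acceptor_selection is not None:
        keep = set(resolve_selection(traj, acceptor_selection).tolist())
        acceptors = acceptors[[int(a) in keep for a in acceptors]]
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("no donors or no acceptors in the selections")
    values = np.array(
        [
            hbond_count_frame(
                traj.coords[t], donors, acceptors, d_cutoff, angle_cutoff
            )
            for t in range(traj.n_frames)
        ],
        dtype=float,
    )
    return MetricSeries(name="HBond", values=values, unit="count")
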