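"""Solvent-accessible surface area by Shrake–Rupley point quadrature.

Each atom is dressed with a quasi-uniform golden-spiral point sphere of
radius r_vdw + r_probe; points buried inside any neighbor's dressed
sphere are excluded, and the accessible fraction times the sphere area
gives the atom's SASA.  Totals are reported in nm² (1 nm² = 100 Å²),
the unit MD practitioners use for whole-protein SASA.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import Trajectory, resolve_selection
from .metrics import MetricSeries

__all__ = ["sphere_points", "sasa_frame", "sasa_series"]


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points via the golden spiral."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [
            np.sin(phi) * np.cos(theta),
            np.sin(phi) * np.sin(theta),
            np.cos(phi),
        ]
    )


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into their principal-axes frame.

    The quadrature sphere is fixed in space, so without this step a
    rigidly rotated frame would sample different surface points and the
    area would wobble by the quadrature error.  Expressing the
    coordinates in the (deterministically signed) principal-axes frame
    makes the computed area exactly invariant under rigid motion.
    """
    c = coords - coords.mean(axis=0)
    if len(c) < 2:
        return c
    evals, vecs = np.linalg.eigh(c.T @ c)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(3):
        proj = c @ vecs[:, k]
        skew = (proj**3).sum()
        sign = np.sign(skew) if abs(skew) > 1e-12 else np.sign(
            proj[np.argmax(np.abs(proj))] or 1.0
        )
        if sign < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return c @ vecs


def sasa_frame(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) for one frame."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    coords = _canonical_orientation(coords)
    n = len(radii)
    dressed = radii + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    # any two atoms whose dressed spheres intersect are mutual occluders
    pairs = tree.query_pairs(2.0 * dressed.max(), output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        if np.linalg.norm(coords[i] - coords[j]) < dressed[i] + dressed[j]:
            neighbors[i].append(j)
            neighbors[j].append(i)

    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + dressed[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors[i]:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > dressed[j] ** 2
        areas[i] = (
            accessible.mean() * 4.0 * np.pi * dressed[i] ** 2
        )
    return areas


def sasa_series(
    traj: Trajectory,
    selection=None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> MetricSeries:
    """Total SASA of the selection per frame, in nm².

    Only the selected atoms participate — both as surface contributors
    and as occluders — matching the convention of computing a complex's
    SASA on its heavy atoms alone.
    """
    idx = resolve_selection(traj, selection)
    radii = traj.atoms["radius"].to_numpy()[idx]
    values = np.array(
        [
            sasa_frame(
                traj.coords[t, idx], radii, probe_radius, n_sphere_points
            ).sum()
            / 100.0
            for t in range(traj.n_frames)
        ]
    )
    return MetricSeries(name="SASA", values=values, unit="nm²")
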