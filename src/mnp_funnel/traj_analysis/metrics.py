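"""Per-frame trajectory metrics: RMSD series, RMSF profile, Rg series.

All three operate after (or independently of) optimal rigid
superposition, so uniform rigid motion of whole frames does not
register as internal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, resolve_selection
from .superpose import apply_transform, kabsch_superpose

__all__ = ["MetricSeries", "RMSFProfile", "rmsd_series", "rmsf", "radius_of_gyration"]


@dataclass
class MetricSeries:
    """A named per-frame series with its mean ± sd summary."""

    name: str
    values: np.ndarray
    unit: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    def summary(self) -> str:
        return f"{self.name}: {self.mean:.3f} ± {self.sd:.3f} {self.unit}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             self.name: self.values})


@dataclass
class RMSFProfile:
    """Per-atom fluctuations (Å), optionally aggregated per residue."""

    atom_indices: np.ndarray
    values: np.ndarray  # per selected atom, Å
    by_residue: pd.Series | None = None  # index: resid, mean over atoms


def _weighted_rmsd(delta: np.ndarray, weights: np.ndarray) -> float:
    msd = (weights[:, None] * delta**2).sum() / weights.sum()
    return float(np.sqrt(msd))


def rmsd_series(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    fit_selection=None,
    calc_selection=None,
    mass_weighted: bool = False,
) -> MetricSeries:
    """RMSD of every frame against a reference after superposition.

    Each frame is rigidly fitted to the reference on ``fit_selection``
    (default: all atoms) and the RMSD is evaluated on
    ``calc_selection`` (default: the fit selection).  ``reference`` is a
    frame index or an explicit (N, 3) coordinate array.
    """
    fit_idx = resolve_selection(traj, fit_selection)
    calc_idx = (
        fit_idx if calc_selection is None
        else resolve_selection(traj, calc_selection)
    )
    ref = (
        traj.coords[reference]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference must cover the full atom set")
    masses = traj.atoms["mass"].to_numpy()
    fit_w = masses[fit_idx] if mass_weighted else np.ones(fit_idx.size)
    calc_w = masses[calc_idx] if mass_weighted else np.ones(calc_idx.size)

    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(
            traj.coords[t, fit_idx], ref[fit_idx], fit_w
        )
        moved = apply_transform(traj.coords[t, calc_idx], rot, trans)
        values[t] = _weighted_rmsd(moved - ref[calc_idx], calc_w)
    return MetricSeries(name="RMSD", values=values, unit="Å")


def superpose_frames(
    traj: Trajectory, fit_selection=None, reference: int = 0, iterations: int = 1
) -> np.ndarray:
    """All frames fitted to the mean structure; returns (F, N, 3).

    Frames are first fitted to ``reference``, then re-fitted to the mean
    structure ``iterations`` times (once is the standard practice).
    """
    fit_idx = resolve_selection(traj, fit_selection)
    out = np.empty_like(traj.coords)
    ref = traj.coords[reference]
    for t in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[t, fit_idx], ref[fit_idx])
        out[t] = apply_transform(traj.coords[t], rot, trans)
    for _ in range(iterations):
        mean = out.mean(axis=0)
        for t in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(out[t, fit_idx], mean[fit_idx])
            out[t] = apply_transform(out[t], rot, trans)
    return out


def rmsf(
    traj: Trajectory,
    selection=None,
    aggregate_by_residue: bool = False,
) -> RMSFProfile:
    """Root-mean-square fluctuation of each selected atom.

    Frames are superposed to the mean structure (one re-fit iteration);
    RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames, in Å.  Residue
    aggregation averages the member atoms' RMSF values.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = resolve_selection(traj, selection)
    fitted = superpose_frames(traj, selection)[:, idx]
    mean = fitted.mean(axis=0)
    values = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    by_residue = None
    if aggregate_by_residue:
        resids = traj.atoms["resid"].to_numpy()[idx]
        by_residue = (
            pd.Series(values, index=pd.Index(resids, name="resid"))
            .groupby(level=0)
            .mean()
        )
    return RMSFProfile(atom_indices=idx, values=values, by_residue=by_residue)


def radius_of_gyration(
    traj: Trajectory, selection=None, mass_weighted: bool = True
) -> MetricSeries:
    """Rg(t) = sqrt(sum m_i |x_i - x_com|^2 / sum m_i), in Å."""
    idx = resolve_selection(traj, selection)
    masses = (
        traj.atoms["mass"].to_numpy()[idx]
        if mass_weighted
        else np.ones(idx.size)
    )
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass of the selection is zero")
    xyz = traj.coords[:, idx, :]
    com = (masses[None, :, None] * xyz).sum(axis=1) / total
    sq = ((xyz - com[:, None, :]) ** 2).sum(axis=2)
    values = np.sqrt((masses[None, :] * sq).sum(axis=1) / total)
    return MetricSeries(name="Rg", values=values, unit="Å")
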