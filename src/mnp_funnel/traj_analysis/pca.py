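"""Essential-dynamics PCA of a trajectory.

Frames are superposed to the mean structure, the 3N-dimensional
centered coordinate vectors are decomposed by SVD (equivalent to
eigen-decomposing the 3N × 3N covariance without forming it), and each
frame is projected onto the leading eigenvectors.  Eigenvalues are in
Å² and sum to the total positional variance (trace conservation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, resolve_selection
from .metrics import superpose_frames

__all__ = ["PCAResult", "pca_project"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # full spectrum, descending, Å²
    eigenvectors: np.ndarray  # (3N, k) leading components, orthonormal
    projections: np.ndarray  # (F, k), Å
    total_variance: float  # Å², trace of the full covariance

    @property
    def pc12(self) -> np.ndarray:
        """Projections onto the first two components, (F, 2)."""
        return self.projections[:, :2]


def pca_project(
    traj: Trajectory, selection=None, n_components: int = 2
) -> PCAResult:
    """Project the trajectory onto its leading principal components.

    Degenerate trajectories (no variance at all) yield zero eigenvalues
    and zero projections rather than an error; fewer than 2 frames is an
    error.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = resolve_selection(traj, selection)
    fitted = superpose_frames(traj, selection)[:, idx]
    f = traj.n_frames
    x = fitted.reshape(f, -1)
    x = x - x.mean(axis=0)
    # covariance C = X^T X / (F - 1); SVD of X gives its spectrum
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (f - 1)
    k = min(n_components, len(eigenvalues))
    eigenvectors = vt[:k].T
    projections = x @ eigenvectors
    if k < n_components:  # pad so callers always get n_components columns
        pad = n_components - k
        eigenvectors = np.column_stack(
            [eigenvectors, np.zeros((x.shape[1], pad))]
        )
        projections = np.column_stack([projections, np.zeros((f, pad))])
    total = float((x**2).sum() / (f - 1))
    return PCAResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        projections=projections,
        total_variance=total,
    )
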