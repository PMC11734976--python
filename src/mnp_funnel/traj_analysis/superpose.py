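"""Least-squares rigid superposition (Kabsch algorithm).

The optimal rotation minimizing weighted RMSD between two centered
point sets is obtained from the SVD of the weighted covariance matrix;
the reflection branch (det = -1) is corrected by flipping the smallest
singular direction so the result is always a proper rotation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_superpose", "apply_transform", "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    """Selection is (nearly) collinear; the rotation is not determined."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation and translation of mobile onto reference.

    Returns ``(rotation, translation, rmsd_after)`` with the convention
    ``aligned = mobile @ rotation.T + translation``.  ``rmsd_after`` is
    the weighted RMSD (Å) after superposition.

    Requires at least three non-collinear points; a collinear point set
    leaves the rotation about the line undetermined and raises
    :class:`DegenerateGeometryError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - mob_c
    y = reference - ref_c

    for pts in (x, y):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[0] == 0 or sv[1] / sv[0] < 1e-8:
            raise DegenerateGeometryError(
                "point set is collinear; rotation is undetermined"
            )

    cov = (w[:, None] * y).T @ x  # 3x3
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rotation = u @ flip @ vt
    translation = ref_c - rotation @ mob_c

    aligned = x @ rotation.T
    msd = (w[:, None] * (aligned - y) ** 2).sum() / wsum
    return rotation, translation, float(np.sqrt(msd))


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return coords @ rotation.T + translation
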