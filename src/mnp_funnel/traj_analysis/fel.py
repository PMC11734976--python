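"""Free-energy landscape over PCA projections.

The 2-D histogram of (PC1, PC2) occupancies is converted to relative
free energies via the inverse Boltzmann relation
ΔG = −k_B·T · ln(P / P_max), so the most populated bin sits at exactly
zero and every other occupied bin is positive.  Empty bins carry no
population information and are masked (and, for plotting/export,
assigned the maximum finite ΔG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann, Avogadro

__all__ = ["FELGrid", "fel_grid"]

_KB_KJ_PER_MOL_K = Boltzmann * Avogadro / 1000.0  # ≈ 0.008314 kJ/(mol·K)


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    delta_g: np.ndarray  # (nx, ny); masked bins hold the max finite ΔG
    mask: np.ndarray  # True where the bin is empty
    unit: str
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = [
            {
                "pc1": xc[i],
                "pc2": yc[j],
                "delta_g": self.delta_g[i, j],
                "empty": bool(self.mask[i, j]),
            }
            for i in range(len(xc))
            for j in range(len(yc))
        ]
        return pd.DataFrame(rows)


def fel_grid(
    projections: np.ndarray,
    bins: int | tuple[int, int] = 50,
    temperature: float = 300.0,
    unit: str = "kT",
    data_range=None,
) -> FELGrid:
    """Free-energy surface from (F, 2) PC projections.

    ``unit`` is ``"kT"`` (ΔG in units of k_B·T) or ``"kJ/mol"``.
    ``data_range`` optionally fixes the histogram extent as
    ``((xmin, xmax), (ymin, ymax))``; by default the data extent is
    used, which must be non-degenerate along both axes.  At least 2 bins
    per axis.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("projections must be (F, 2) with F >= 1")
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    if data_range is None:
        for axis in range(2):
            if np.ptp(pts[:, axis]) == 0.0:
                raise ValueError(
                    f"zero-width data range along axis {axis}; cannot bin"
                )
    if unit == "kT":
        kt = 1.0
    elif unit == "kJ/mol":
        kt = _KB_KJ_PER_MOL_K * temperature
    else:
        raise ValueError("unit must be 'kT' or 'kJ/mol'")

    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, range=data_range
    )
    mask = counts == 0
    delta_g = np.zeros_like(counts)
    occupied = ~mask
    delta_g[occupied] = -kt * np.log(counts[occupied] / counts.max())
    fill = delta_g[occupied].max() if occupied.any() else 0.0
    delta_g[mask] = fill
    return FELGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        delta_g=delta_g,
        mask=mask,
        unit=unit,
        temperature=temperature,
    )
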