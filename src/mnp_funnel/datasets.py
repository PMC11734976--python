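"""Bundled reference data.

Ships the published CDK4/6 marine-natural-product consensus docking
campaign: binding scores of 25 toxicity-filtered compounds under seven
docking programs (AutoDockTools 4.2, LeDock, Qvina 2, Smina, AutoDock
Vina 1.2.0, PLANTS, rDock; all columns lower-is-better) and the
corresponding published competition-rank table, used as a regression
reference for the Rank-by-Rank implementation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus_ranker import ScoreTable

#: Active-site residue numbers of the CDK4/6 target (PDB 5L2S):
#: ILE19, TYR24, ALA41, GLU99, GLN103, ASP104, ALA162.
CDK46_ACTIVE_SITE_RESIDS = (19, 24, 41, 99, 103, 104, 162)

#: The six consensus-docking shortlist compounds taken into MD follow-up.
CDK46_SHORTLIST = frozenset(
    {
        "205813-99-6",
        "223130-61-8",
        "CMNPD11585",
        "CMNPD14217",
        "CMNPD2744",
        "CMNPD7986",
    }
)


def _read_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("mnp_funnel.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)


def load_reference_scores() -> ScoreTable:
    """The 25 x 7 consensus docking score matrix (kcal/mol or native units)."""
    return ScoreTable.from_frame(_read_bundled("cdk46_scores.csv"))


def load_reference_ranks() -> pd.DataFrame:
    """The published 25 x 7 competition-rank table for the same campaign."""
    return _read_bundled("cdk46_ranks.csv").astype(int)
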