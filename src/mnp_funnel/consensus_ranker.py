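"""Consensus docking rank aggregation (Rank-by-Rank).

A virtual-screening campaign that docks the same compounds with several
programs produces a compounds × programs score matrix in which every
program's scale is different (kcal/mol binding energies, PLANTS or rDock
native scores).  Rank-by-Rank (RbR) makes the columns commensurable by
replacing each score with its within-program competition rank (best
score → rank 1, ties share the minimal rank of their block) and then
averaging each compound's ranks across programs; the compounds with the
lowest mean rank form the consensus shortlist.

Competition ("1224") ranking is used because it is what tied scores in
published consensus tables produce: two compounds tied at the 24th-best
score both get rank 24 and no rank 25 is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoreTable",
    "ConsensusRanking",
    "score_threshold_filter",
    "competition_rank",
    "rank_by_rank",
    "select_top",
]


class NonFiniteScoreError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Compounds × programs docking score matrix.

    ``orientation`` flags, one per program, mark whether lower scores are
    better (the default for every common docking score).  A program whose
    flag is ``False`` has its column negated before ranking.
    """

    compounds: list[str]
    programs: list[str]
    scores: np.ndarray  # shape (n_compounds, n_programs)
    lower_is_better: list[bool] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n, m = len(self.compounds), len(self.programs)
        if n < 1 or m < 1:
            raise ValueError("score table needs at least one compound and one program")
        if self.scores.shape != (n, m):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{n} compounds x {m} programs"
            )
        if len(set(self.compounds)) != n:
            raise ValueError("compound ids must be unique")
        if len(set(self.programs)) != m:
            raise ValueError("program ids must be unique")
        if self.lower_is_better is None:
            self.lower_is_better = [True] * m
        if not np.isfinite(self.scores).all():
            bad = [
                self.compounds[i]
                for i in np.argwhere(~np.isfinite(self.scores))[:, 0]
            ]
            raise NonFiniteScoreError(
                f"non-finite score(s) for compound(s): {sorted(set(bad))}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kw) -> "ScoreTable":
        """Build from a DataFrame indexed by compound id, one column per program."""
        return cls(
            compounds=[str(c) for c in frame.index],
            programs=[str(p) for p in frame.columns],
            scores=frame.to_numpy(dtype=float),
            **kw,
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "ScoreTable":
        """Read a CSV whose first column is the compound id, header = programs."""
        return cls.from_frame(pd.read_csv(path, index_col=0), **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.compounds, columns=self.programs
        ).rename_axis("compound")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class ConsensusRanking:
    """Result of Rank-by-Rank aggregation."""

    mean_rank: pd.Series  # indexed by compound id, original row order
    ordering: list[str]  # compounds sorted ascending by mean rank
    rank_table: pd.DataFrame  # compounds x programs competition ranks
    selected: list[str] = field(default_factory=list)


def score_threshold_filter(
    scores: Mapping[str, float], cutoff: float
) -> set[str]:
    """Initial-hit selection: keep ids scoring at or below the cutoff.

    Scores are binding energies (kcal/mol); more negative binds stronger,
    and a score exactly at the cutoff is retained (``<=`` semantics).
    """
    bad = [i for i, s in scores.items() if not np.isfinite(s)]
    if bad:
        raise NonFiniteScoreError(f"non-finite score(s) for: {sorted(bad)}")
    return {i for i, s in scores.items() if s <= cutoff}


def competition_rank(
    values: Sequence[float], lower_is_better: bool = True
) -> np.ndarray:
    """Competition ("1224") ranks of one score column.

    The best value gets rank 1; tied values share the minimal rank of
    their tie block, and the following value's rank counts the full
    block, so n values with k ties never use rank n when k > 1.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise NonFiniteScoreError(
            f"non-finite value(s) at position(s) "
            f"{np.argwhere(~np.isfinite(v))[:, 0].tolist()}"
        )
    if not lower_is_better:
        v = -v
    return rankdata(v, method="min").astype(int)


def rank_by_rank(table: ScoreTable) -> ConsensusRanking:
    """Aggregate a score table into a consensus ordering.

    Each program's column is competition-ranked, the per-compound mean
    rank over the m programs is taken, and compounds are ordered by
    ascending mean rank.  Exact mean-rank ties are broken by the best
    single-program rank, then lexicographically by compound id, purely to
    make the ordering deterministic.
    """
    ranks = np.column_stack(
        [
            competition_rank(table.scores[:, j], table.lower_is_better[j])
            for j in range(len(table.programs))
        ]
    )
    rank_table = pd.DataFrame(
        ranks, index=table.compounds, columns=table.programs
    ).rename_axis("compound")
    mean_rank = rank_table.mean(axis=1)
    order_key = sorted(
        table.compounds,
        key=lambda c: (mean_rank[c], int(rank_table.loc[c].min()), c),
    )
    return ConsensusRanking(
        mean_rank=mean_rank, ordering=order_key, rank_table=rank_table
    )


def select_top(cons: ConsensusRanking, n: int) -> list[str]:
    """Pick the n best compounds by mean rank for follow-up.

    If a block of compounds with exactly equal mean rank straddles the
    cut at position n, the whole block is included, so the returned list
    may exceed n — a tie is never split.
    """
    total = len(cons.ordering)
    if not 1 <= n <= total:
        raise ValueError(f"n must be in 1..{total}, got {n}")
    selected = list(cons.ordering[:n])
    cut_value = cons.mean_rank[selected[-1]]
    for comp in cons.ordering[n:]:
        if cons.mean_rank[comp] == cut_value:
            selected.append(comp)
        else:
            break
    cons.selected = selected
    return selected
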