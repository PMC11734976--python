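"""Synthetic docking score tables with a planted true ranking.

Emulates the structure of a consensus docking campaign: every program
scores every compound, all columns lower-is-better, and each program
sees the same underlying affinity ordering corrupted by its own
Gaussian score noise.  With zero noise every program's competition
ranking equals the planted truth, so Rank-by-Rank recovers it exactly;
with noise the mean-rank ordering is a better estimator of the truth
than any single program — the property consensus ranking exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..consensus_ranker import ScoreTable

__all__ = ["ScoreModel", "gen_score_table"]

_DEFAULT_PROGRAMS = (
    "prog1",
    "prog2",
    "prog3",
    "prog4",
    "prog5",
    "prog6",
    "prog7",
)


@dataclass
class ScoreModel:
    """Generative model for one synthetic score table.

    ``true_ranking[i]`` is the true rank (1 = strongest binder) of
    compound i and must be a permutation of 1..n.  Scores are
    ``base_score - (n - true_rank + 1) + Normal(0, sd_p)`` so that the
    true best compound has the most negative noise-free score and
    adjacent ranks sit one score unit apart.
    """

    n_compounds: int
    programs: Sequence[str] = _DEFAULT_PROGRAMS
    true_ranking: Sequence[int] | None = None
    noise_sd_per_program: Sequence[float] | float = 0.0
    base_score: float = -7.0
    seed: int = 0
    compound_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_compounds
        if n < 1:
            raise ValueError("n_compounds must be positive")
        if self.true_ranking is None:
            self.true_ranking = list(range(1, n + 1))
        if sorted(self.true_ranking) != list(range(1, n + 1)):
            raise ValueError("true_ranking must be a permutation of 1..n")
        m = len(self.programs)
        if np.isscalar(self.noise_sd_per_program):
            self.noise_sd_per_program = [float(self.noise_sd_per_program)] * m
        if len(self.noise_sd_per_program) != m:
            raise ValueError("need one noise sd per program")
        if any(sd < 0 for sd in self.noise_sd_per_program):
            raise ValueError("noise sd must be non-negative")
        if not self.compound_ids:
            self.compound_ids = [f"SYN{i:04d}" for i in range(n)]
        if len(self.compound_ids) != n:
            raise ValueError("need one compound id per compound")


def gen_score_table(model: ScoreModel) -> ScoreTable:
    """Draw one score table from the model (deterministic in the seed)."""
    rng = np.random.default_rng(model.seed)
    n = model.n_compounds
    ranks = np.asarray(model.true_ranking, dtype=float)
    clean = model.base_score - (n - ranks + 1.0)
    sds = np.asarray(model.noise_sd_per_program, dtype=float)
    noise = rng.normal(0.0, 1.0, size=(n, len(sds))) * sds[None, :]
    scores = clean[:, None] + noise
    return ScoreTable(
        compounds=list(model.compound_ids),
        programs=list(model.programs),
        scores=scores,
    )
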