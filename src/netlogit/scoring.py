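"""Percentile decision scores and reproducible rankings.

Raw posteriors are hard to threshold across diseases, so each unknown
gene's posterior p_i is converted to its self-inclusive top-percentage
value among all n unknown genes:

    q_i = |{ j : p_i >= p_j }| / n

q_i lies in (0, 1]; tied posteriors share the same (higher) percentile, the
only reading consistent with the ``>=`` in the formula.  q depends on the
posteriors only through their order, so any strictly increasing transform
of p leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["DecisionScores", "percentile_scores", "decision_scores"]


def percentile_scores(posteriors: np.ndarray) -> np.ndarray:
    """Self-inclusive percentile q_i = |{j : p_i >= p_j}| / n."""
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise ValueError("decision scores need at least one posterior")
    return rankdata(p, method="max") / p.size


@dataclass(frozen=True)
class DecisionScores:
    """Decision scores for the unknown genes of one disease run."""

    genes: tuple[str, ...]
    posterior: np.ndarray
    score: np.ndarray
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.genes) == self.posterior.size == self.score.size):
            raise ValueError("genes, posteriors and scores must align")

    @property
    def n(self) -> int:
        return len(self.genes)

    def rank(self) -> np.ndarray:
        """1-based rank by score descending, ties broken by gene id ascending."""
        order = sorted(range(self.n), key=lambda i: (-self.score[i], self.genes[i]))
        ranks = np.empty(self.n, dtype=int)
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        return ranks

    def records(self) -> list[tuple[str, float, float, int]]:
        """(gene, posterior, decision score, rank) rows for the ranking writer."""
        ranks = self.rank()
        return [
            (self.genes[i], float(self.posterior[i]), float(self.score[i]), int(ranks[i]))
            for i in range(self.n)
        ]

    def score_of(self, gene: str) -> float:
        return float(self.score[self.genes.index(gene)])


def decision_scores(
    posteriors: np.ndarray,
    genes: Sequence[str] | None = None,
    **provenance: object,
) -> DecisionScores:
    """Convert unknown-gene posteriors into percentile decision scores.

    Output order matches input order; ``genes`` defaults to positional
    labels when the caller works with anonymous vectors.
    """
    p = np.asarray(posteriors, dtype=float)
    q = percentile_scores(p)
    if genes is None:
        genes = tuple(f"g{i}" for i in range(p.size))
    return DecisionScores(
        genes=tuple(genes), posterior=p, score=q, provenance=dict(provenance)
    )
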