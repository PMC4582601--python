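"""Prior probability estimation and prior label sampling.

For a target disease class d_k, every gene needs a prior probability of
carrying label 1 before the regression is fitted:

* known genes are fixed — prior 1 if associated with d_k, 0 if known only
  for other diseases;
* unknown genes get either the zero prior (strategy ``P0``) or a protein
  complex prior (strategy ``Pc``): if the gene sits in at least one complex
  containing known disease genes, its prior is the maximum over its
  complexes of A/B, where A counts the complex's known genes of d_k and B
  counts the complex's known disease genes of any disease; a gene in no such
  complex falls back to the genome-wide base rate C/D, with C the number of
  known d_k genes and D the genome size (the universe size by default).

Prior labels are then drawn per gene as independent Bernoulli variables
(uniform u in [0,1); label 1 iff u < prior), with the draws attached to gene
identifiers in lexicographic order so that re-partitioning the universe
(e.g. demoting a held-out gene) never shifts another gene's draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .containers import DiseaseGeneMap, GeneSetCollection, GeneUniverse

logger = logging.getLogger("netlogit")

__all__ = [
    "PriorAssignment",
    "complex_prior",
    "zero_prior",
    "set_known_labels",
    "sample_prior_labels",
    "prior_vector",
]

STRATEGIES = ("P0", "Pc")


@dataclass(frozen=True)
class PriorAssignment:
    """Per-gene prior probabilities and one sampled binary configuration."""

    p_hat: np.ndarray
    x_hat: np.ndarray
    strategy: str
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_hat, dtype=float)
        x = np.asarray(self.x_hat, dtype=float)
        if p.shape != x.shape:
            raise ValueError("p_hat and x_hat shapes differ")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("prior probabilities must lie in [0, 1]")
        if not np.all(np.isin(x, (0.0, 1.0))):
            raise ValueError("prior labels must be binary")
        object.__setattr__(self, "p_hat", p)
        object.__setattr__(self, "x_hat", x)


def complex_prior(
    gene: str,
    complexes: GeneSetCollection,
    disease_genes_of_dk: Iterable[str],
    all_disease_genes: Iterable[str],
    C: int,
    D: int,
) -> float:
    """Protein-complex prior for a single (unknown) gene.

    Returns max over the gene's complexes of A/B (A = complex members known
    for the target disease, B = complex members known for any disease),
    falling back to C/D when the gene is in no complex or every one of its
    complexes contains no known disease gene (B = 0, ratio undefined).
    """
    if D < 1:
        raise ValueError("genome size D must be >= 1")
    if C > D:
        raise ValueError("C cannot exceed the genome size D")
    dk = frozenset(disease_genes_of_dk)
    known = frozenset(all_disease_genes)
    best: float | None = None
    for name in complexes:
        members = complexes[name]
        if gene not in members:
            continue
        b = len(members & known)
        if b == 0:
            continue
        a = len(members & dk)
        ratio = a / b
        if best is None or ratio > best:
            best = ratio
    if best is None:
        return C / D
    return best


def zero_prior(universe: GeneUniverse) -> np.ndarray:
    """Zero prior (strategy P0) for the unknown genes."""
    return np.zeros(universe.n, dtype=float)


def set_known_labels(
    universe: GeneUniverse, disease_map: DiseaseGeneMap, d_k: str
) -> np.ndarray:
    """Fixed priors over the known genes: 1 for genes of d_k, else 0."""
    if d_k not in disease_map:
        raise KeyError(f"unknown disease class {d_k!r}")
    members = disease_map[d_k]
    if not members:
        logger.warning("disease class %r has no member genes", d_k)
    return np.array(
        [1.0 if g in members else 0.0 for g in universe.known_genes()], dtype=float
    )


def prior_vector(
    universe: GeneUniverse,
    disease_map: DiseaseGeneMap,
    d_k: str,
    strategy: str = "P0",
    complexes: GeneSetCollection | None = None,
    genome_size: int | None = None,
) -> np.ndarray:
    """Full-length prior vector over the universe's canonical order."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown prior strategy {strategy!r}")
    known_part = set_known_labels(universe, disease_map, d_k)
    if strategy == "P0":
        unknown_part = zero_prior(universe)
    else:
        if complexes is None:
            raise ValueError("strategy Pc requires a complex collection")
        dk_genes = disease_map[d_k] & set(universe.known_genes())
        all_known = frozenset(universe.known_genes())
        D = genome_size if genome_size is not None else universe.N
        C = len(dk_genes)
        unknown_part = np.array(
            [
                complex_prior(g, complexes, dk_genes, all_known, C, D)
                for g in universe.unknown_genes()
            ],
            dtype=float,
        )
    return np.concatenate([unknown_part, known_part])


def sample_prior_labels(
    p_hat: np.ndarray,
    rng: np.random.Generator,
    universe: GeneUniverse | None = None,
) -> np.ndarray:
    """Draw one binary prior configuration from per-gene priors.

    Each gene's label is an independent Bernoulli(p_hat) draw realized as
    ``u < p_hat`` with u uniform on [0,1), so priors of exactly 0 or 1 give
    deterministic labels for any seed.  When a ``universe`` is supplied the
    uniform stream is consumed in lexicographic gene order, making the draw
    for a given gene identifier independent of the unknown/known partition.
    """
    p = np.asarray(p_hat, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prior probabilities must lie in [0, 1]")
    u_stream = rng.random(p.size)
    if universe is not None:
        if universe.N != p.size:
            raise ValueError("prior vector length does not match universe size")
        u = np.empty(p.size)
        u[universe.lexicographic_order] = u_stream
    else:
        u = u_stream
    return (u < p).astype(float)


def assemble(
    universe: GeneUniverse,
    disease_map: DiseaseGeneMap,
    d_k: str,
    strategy: str,
    rng: np.random.Generator,
    complexes: GeneSetCollection | None = None,
    genome_size: int | None = None,
    seed: int | None = None,
) -> PriorAssignment:
    """Convenience wrapper: estimate priors and sample one configuration."""
    p = prior_vector(universe, disease_map, d_k, strategy, complexes, genome_size)
    x = sample_prior_labels(p, rng, universe)
    return PriorAssignment(p_hat=p, x_hat=x, strategy=strategy, seed=seed)
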