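"""In-memory domain containers.

The whole pipeline operates on four containers: an ordered
:class:`GeneUniverse` (unknown genes first, known disease genes last), a
:class:`DiseaseGeneMap` linking disease classes to their known genes, a
:class:`GeneSetCollection` used for both protein complexes and pathways,
and an :class:`ExpressionMatrix` for co-expression network construction.
File parsing lives in :mod:`netlogit.io`; everything downstream consumes
these types only.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import DataFormatError

__all__ = [
    "GeneUniverse",
    "DiseaseGeneMap",
    "GeneSetCollection",
    "ExpressionMatrix",
]


class GeneUniverse:
    """Ordered set of gene identifiers partitioned into unknown and known genes.

    The canonical ordering places the ``n`` unknown genes (no known disease
    association) before the ``m`` known disease genes; within each block genes
    are sorted lexicographically, so every downstream index is reproducible.

    Parameters
    ----------
    genes
        Unique, non-empty gene identifiers in an order already satisfying the
        unknown-before-known invariant (use :meth:`from_known` to build the
        canonical ordering from unordered inputs).
    known_mask
        Boolean per-gene flag; ``True`` marks a known disease gene.
    """

    __slots__ = ("_genes", "_known", "_index", "_lex")

    def __init__(self, genes: Iterable[str], known_mask: Iterable[bool]):
        gene_tuple = tuple(str(g) for g in genes)
        known = np.asarray(list(known_mask), dtype=bool)
        if len(gene_tuple) == 0:
            raise DataFormatError("gene universe must contain at least one gene")
        if known.shape != (len(gene_tuple),):
            raise DataFormatError("known_mask length does not match gene count")
        if any(not g for g in gene_tuple):
            raise DataFormatError("empty gene identifier in universe")
        if len(set(gene_tuple)) != len(gene_tuple):
            raise DataFormatError("duplicate gene identifiers in universe")
        if np.any(np.diff(known.astype(np.int8)) < 0):
            raise DataFormatError(
                "universe ordering violated: all unknown genes must precede "
                "all known genes"
            )
        self._genes = gene_tuple
        known.setflags(write=False)
        self._known = known
        self._index = {g: i for i, g in enumerate(gene_tuple)}
        lex = np.argsort(np.asarray(gene_tuple, dtype=object))
        lex.setflags(write=False)
        self._lex = lex

    @classmethod
    def from_known(
        cls, genes: Iterable[str], known_genes: Iterable[str]
    ) -> "GeneUniverse":
        """Build the canonical universe from a gene pool and its known subset."""
        pool = sorted({str(g) for g in genes})
        known = {str(g) for g in known_genes}
        missing = known - set(pool)
        if missing:
            raise DataFormatError(
                f"{len(missing)} known genes absent from the gene pool "
                f"(e.g. {sorted(missing)[:3]})"
            )
        ordered = [g for g in pool if g not in known] + [g for g in pool if g in known]
        return cls(ordered, [g in known for g in ordered])

    # -- basic protocol ----------------------------------------------------
    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def known_mask(self) -> np.ndarray:
        """Read-only boolean mask; ``True`` = known disease gene."""
        return self._known

    @property
    def N(self) -> int:
        return len(self._genes)

    @property
    def m(self) -> int:
        return int(self._known.sum())

    @property
    def n(self) -> int:
        return self.N - self.m

    def __len__(self) -> int:
        return self.N

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneUniverse)
            and self._genes == other._genes
            and bool(np.array_equal(self._known, other._known))
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneUniverse(N={self.N}, n={self.n}, m={self.m})"

    def index(self, gene: str) -> int:
        """Position of ``gene`` in the canonical ordering."""
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in universe") from None

    @property
    def lexicographic_order(self) -> np.ndarray:
        """Universe positions sorted by gene identifier.

        Stochastic per-gene draws are made in this order so they attach to
        gene *names*, not to positions that shift when a gene is demoted.
        """
        return self._lex

    def known_genes(self) -> tuple[str, ...]:
        return self._genes[self.n :]

    def unknown_genes(self) -> tuple[str, ...]:
        return self._genes[: self.n]

    def demote(self, gene: str) -> "GeneUniverse":
        """Return a new canonical universe with ``gene`` moved to the unknowns.

        Used by the leave-one-out protocol: the held-out gene loses its known
        status entirely, so ``n`` grows and ``m`` shrinks by one.
        """
        i = self.index(gene)
        if not self._known[i]:
            raise ValueError(f"gene {gene!r} is already unknown")
        known = set(self.known_genes())
        known.discard(gene)
        return GeneUniverse.from_known(self._genes, known)


class DiseaseGeneMap(Mapping[str, frozenset]):
    """Mapping from disease-class identifier to its set of known genes."""

    def __init__(self, classes: Mapping[str, Iterable[str]]):
        self._classes: dict[str, frozenset] = {
            str(k): frozenset(str(g) for g in v) for k, v in classes.items()
        }

    def __getitem__(self, disease: str) -> frozenset:
        return self._classes[disease]

    def __iter__(self) -> Iterator[str]:
        return iter(self._classes)

    def __len__(self) -> int:
        return len(self._classes)

    def genes(self) -> frozenset:
        """Union of all class gene sets (the known disease genes)."""
        return frozenset().union(*self._classes.values()) if self._classes else frozenset()

    def restricted(self, universe: GeneUniverse) -> tuple["DiseaseGeneMap", int]:
        """Drop mapped genes absent from ``universe``; return (map, n_dropped)."""
        dropped = 0
        kept: dict[str, frozenset] = {}
        for k, members in self._classes.items():
            inside = frozenset(g for g in members if g in universe)
            dropped += len(members) - len(inside)
            kept[k] = inside
        return DiseaseGeneMap(kept), dropped

    def validate_against(self, universe: GeneUniverse) -> None:
        """Check the map/universe invariants.

        Every mapped gene must be a known gene of the universe and every known
        gene must belong to at least one class.
        """
        known = set(universe.known_genes())
        mapped = self.genes()
        not_known = mapped - known
        if not_known:
            raise DataFormatError(
                f"{len(not_known)} mapped genes are not known genes of the "
                f"universe (e.g. {sorted(not_known)[:3]})"
            )
        uncovered = known - mapped
        if uncovered:
            raise DataFormatError(
                f"{len(uncovered)} known genes appear in no disease class "
                f"(e.g. {sorted(uncovered)[:3]})"
            )


class GeneSetCollection(Mapping[str, frozenset]):
    """Named gene sets (protein complexes or pathways), each with >= 2 members."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        out: dict[str, frozenset] = {}
        for name, members in sets.items():
            s = frozenset(str(g) for g in members)
            if len(s) < 2:
                raise DataFormatError(
                    f"gene set {name!r} has fewer than 2 distinct members"
                )
            out[str(name)] = s
        self._sets = out

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def genes(self) -> frozenset:
        return frozenset().union(*self._sets.values()) if self._sets else frozenset()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets


class ExpressionMatrix:
    """Gene x sample real-valued expression matrix backed by a DataFrame."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise DataFormatError("duplicate gene identifiers in expression matrix")
        if data.isna().any().any():
            raise DataFormatError("missing values in expression matrix")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataFormatError("non-numeric entries in expression matrix")
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(str(g) for g in self._data.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._data.equals(other._data)
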