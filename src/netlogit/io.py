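"""Readers and writers for the on-disk formats the tool consumes and emits.

All formats are plain text: two-column edge lists (tab or space separated),
GMT gene sets (tab separated: name, description, members...), two-column
disease-association TSV (class_id, gene), TSV expression matrices (first
column gene, header row samples) and the TSV ranking output.  Lines starting
with ``#`` are comments.  Gene identifiers are case-sensitive and used
verbatim; no accession mapping is performed.
"""

from __future__ import annotations

import logging
import math
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd

from .containers import DiseaseGeneMap, ExpressionMatrix, GeneSetCollection, GeneUniverse
from .exceptions import DataFormatError

logger = logging.getLogger("netlogit")

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "read_disease_associations",
    "write_disease_associations",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "write_gene_list",
    "write_ranking",
    "read_ranking",
]


def _lines(path: str | PathLike) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | PathLike) -> list[tuple[str, str]]:
    """Read a raw edge multiset, verbatim and order-preserving.

    Duplicates and self-loops are retained; cleaning is a separate step
    (:func:`netlogit.networks.clean_network`).
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in _lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise DataFormatError(f"{path}: line {lineno}: expected two gene tokens")
        edges.append((tokens[0], tokens[1]))
    if not edges:
        logger.warning("%s: empty edge list", path)
    return edges


def write_edge_list(path: str | PathLike, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_gene_sets(path: str | PathLike) -> GeneSetCollection:
    """Read GMT gene sets: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are collapsed; sets with fewer than two
    distinct members are rejected with a warning (not fatal).  Duplicate set
    names are an error.
    """
    sets: dict[str, frozenset] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataFormatError(
                f"{path}: line {lineno}: GMT line needs name, description and "
                f"at least one member"
            )
        name = fields[0]
        if name in sets:
            raise DataFormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        members = frozenset(t for t in fields[2:] if t)
        if len(members) < 2:
            logger.warning(
                "%s: line %d: gene set %r has <2 distinct members; skipped",
                path, lineno, name,
            )
            continue
        sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(path: str | PathLike, sets: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_disease_associations(
    path: str | PathLike, universe: GeneUniverse | None = None
) -> DiseaseGeneMap:
    """Read a two-column TSV of (disease class, gene) associations.

    Duplicate rows collapse (set semantics).  If a ``universe`` is supplied,
    genes outside it are dropped with a logged count.
    """
    classes: dict[str, set] = {}
    for lineno, line in _lines(path):
        tokens = line.split("\t") if "\t" in line else line.split()
        if len(tokens) < 2:
            raise DataFormatError(
                f"{path}: line {lineno}: expected disease and gene columns"
            )
        classes.setdefault(tokens[0], set()).add(tokens[1])
    dmap = DiseaseGeneMap(classes)
    if universe is not None:
        dmap, dropped = dmap.restricted(universe)
        if dropped:
            logger.warning(
                "%s: dropped %d association(s) to genes outside the universe",
                path, dropped,
            )
    return dmap


def write_disease_associations(path: str | PathLike, dmap: DiseaseGeneMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for disease in sorted(dmap):
            for gene in sorted(dmap[disease]):
                fh.write(f"{disease}\t{gene}\n")


def read_expression_matrix(path: str | PathLike) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene, header row samples."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except ValueError as exc:
        raise DataFormatError(f"{path}: cannot parse expression matrix: {exc}") from exc
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise DataFormatError(
            f"{path}: non-numeric expression column(s): {non_numeric[:3]}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame)


def write_expression_matrix(path: str | PathLike, expr: ExpressionMatrix) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_gene_list(path: str | PathLike) -> list[str]:
    """Read one gene identifier per line."""
    return [line.split()[0] for _, line in _lines(path)]


def write_gene_list(path: str | PathLike, genes: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


_RANKING_COLUMNS = ("gene", "posterior", "decision_score", "rank")


def write_ranking(
    path: str | PathLike, records: Sequence[tuple[str, float, float, int]]
) -> None:
    """Write the per-gene ranking TSV.

    Rows are sorted by decision score descending, ties broken by gene
    identifier ascending; floats are written with 6 significant digits so a
    read/write round trip is the identity at that precision.
    """
    ordered = sorted(records, key=lambda r: (-r[2], r[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RANKING_COLUMNS) + "\n")
        for gene, posterior, score, rank in ordered:
            fh.write(f"{gene}\t{posterior:.6g}\t{score:.6g}\t{rank:d}\n")


def read_ranking(path: str | PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_RANKING_COLUMNS) - set(frame.columns)
    if missing:
        raise DataFormatError(f"{path}: ranking file missing columns {sorted(missing)}")
    return frame


def significant_round(x: float, digits: int = 6) -> float:
    """Round ``x`` to ``digits`` significant digits (ranking precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{digits}g}")
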