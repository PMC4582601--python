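"""Construction and cleaning of the biological networks.

Three kinds of networks feed the prioritization: protein-protein interaction
networks read directly from edge lists, a pathway co-existence network (two
genes linked if they co-occur in at least one pathway gene set), and a gene
co-expression network (two genes linked if their Pearson correlation across
samples strictly exceeds a threshold, 0.5 by default).  All networks are
simple undirected graphs: self-loops and duplicate edges are removed, and
after restriction to a gene universe every universe gene is present, possibly
isolated, so each gene has a well-defined (zero) feature row.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, GeneSetCollection, GeneUniverse
from .exceptions import DataFormatError

logger = logging.getLogger("netlogit")

__all__ = [
    "Network",
    "clean_network",
    "build_pathway_network",
    "build_coexpression_network",
    "vertex_filter",
    "restrict_to_universe",
]


class Network:
    """Simple undirected graph over gene identifiers.

    Invariants: no self-loops, no duplicate edges.  Isolated vertices are
    allowed and meaningful (a gene can be declared present in a data source
    without interactions).
    """

    __slots__ = ("_graph",)

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        vertices: Iterable[str] = (),
    ):
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in vertices)
        g.add_edges_from(
            (str(a), str(b)) for a, b in edges if str(a) != str(b)
        )
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def vertices(self) -> frozenset:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset:
        """Edges as unordered pairs, canonicalized to sorted tuples."""
        return frozenset(tuple(sorted(e)) for e in self._graph.edges)

    @property
    def n_vertices(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def neighbors(self, gene: str) -> set:
        return set(self._graph.neighbors(gene)) if gene in self._graph else set()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Network)
            and self.vertices == other.vertices
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Network(V={self.n_vertices}, E={self.n_edges})"

    def adjacency(self, universe: GeneUniverse) -> sp.csr_array:
        """0/1 adjacency in the universe's canonical gene order.

        Genes absent from the network get all-zero rows; edges touching
        genes outside the universe are ignored.
        """
        rows: list[int] = []
        cols: list[int] = []
        for a, b in self._graph.edges:
            if a in universe and b in universe:
                ia, ib = universe.index(a), universe.index(b)
                rows.extend((ia, ib))
                cols.extend((ib, ia))
        data = np.ones(len(rows), dtype=np.float64)
        return sp.csr_array(
            (data, (rows, cols)), shape=(universe.N, universe.N)
        )

    def second_order_adjacency(self, universe: GeneUniverse) -> sp.csr_array:
        """0/1 matrix marking vertex pairs at shortest-path distance exactly 2."""
        a = self.adjacency(universe)
        walk2 = _drop_diagonal(a @ a)
        reach2 = (walk2 > 0).astype(np.float64)
        # drop pairs that are also direct neighbors
        dist2 = sp.csr_array(reach2 - reach2.multiply(a))
        dist2.eliminate_zeros()
        return dist2

    def walk2_matrix(self, universe: GeneUniverse) -> sp.csr_array:
        """Length-2 walk counts with the diagonal removed (alternative
        second-order semantics; direct neighbors reachable in two steps are
        counted, once per intermediate vertex)."""
        a = self.adjacency(universe)
        return _drop_diagonal(a @ a)


def _drop_diagonal(m: sp.sparray) -> sp.csr_array:
    m = sp.csr_array(m)
    out = m - sp.diags_array(m.diagonal(), format="csr")
    out = sp.csr_array(out)
    out.eliminate_zeros()
    return out


def clean_network(
    raw_edges: Iterable[tuple[str, str]], vertices: Iterable[str] = ()
) -> Network:
    """Drop self-loops and collapse duplicate/reversed edges.

    ``vertices`` optionally declares genes that must be present even if
    isolated (e.g. the node list of a data source).
    """
    return Network(raw_edges, vertices)


def build_pathway_network(pathways: GeneSetCollection) -> Network:
    """Link every unordered gene pair that co-exists in at least one pathway.

    Each pathway contributes a clique; overlapping pathways collapse to
    single edges.
    """
    net = Network()
    for name in pathways:
        members = sorted(pathways[name])
        net.graph.add_nodes_from(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                net.graph.add_edge(a, b)
    return net


def build_coexpression_network(
    expr: ExpressionMatrix, threshold: float = 0.5
) -> Network:
    """Link gene pairs whose Pearson correlation strictly exceeds ``threshold``.

    Requires at least 3 samples.  Genes with zero expression variance have an
    undefined correlation and receive no edges.
    """
    if expr.n_samples < 3:
        raise DataFormatError(
            f"co-expression needs >=3 samples, got {expr.n_samples}"
        )
    values = expr.values
    genes = expr.genes
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    ii, jj = np.nonzero(np.triu(corr > threshold, k=1))
    edges = [(genes[i], genes[j]) for i, j in zip(ii, jj)]
    return Network(edges, vertices=genes)


def vertex_filter(
    networks: Sequence[Network], min_count: int = 4
) -> frozenset:
    """Genes present (as vertices) in at least ``min_count`` of the networks.

    Mirrors the source-agreement filter applied when integrating several
    networks: keep only genes supported by most data sources.
    """
    if not networks:
        raise ValueError("vertex_filter needs at least one network")
    if min_count > len(networks):
        logger.warning(
            "vertex_filter: min_count=%d exceeds the %d supplied networks; "
            "result is empty", min_count, len(networks),
        )
        return frozenset()
    counts: dict[str, int] = {}
    for net in networks:
        for v in net.vertices:
            counts[v] = counts.get(v, 0) + 1
    return frozenset(v for v, c in counts.items() if c >= min_count)


def restrict_to_universe(network: Network, universe: GeneUniverse) -> Network:
    """Clip a network to a universe, keeping every universe gene as a vertex.

    Edges touching genes outside the universe are removed; universe genes
    missing from the network become isolated vertices so every gene has a
    defined zero feature row.
    """
    edges = [
        (a, b) for a, b in network.graph.edges if a in universe and b in universe
    ]
    return Network(edges, vertices=universe.genes)
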