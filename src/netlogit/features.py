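"""Label-count feature matrices built from networks and a prior configuration.

Given a binary label per gene, every gene's feature vector counts how many
of its network neighbors carry each label:

* ``F1`` (one network, 3 columns): intercept, direct neighbors with label 1,
  direct neighbors with label 0.
* ``F2`` (one network, 5 columns): F1 plus the same two counts over the
  second-order neighborhood — vertices at shortest-path distance exactly 2
  (an alternative length-2-walk counting rule is available via
  ``second_order="walks2"``).
* ``F3`` (l networks, 2l+1 columns): intercept, then the direct-neighbor
  label-1/label-0 counts of each network in input order.

Counts are raw integers, deliberately unscaled: any standardization would
change the fitted weights and with them the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .containers import GeneUniverse
from .networks import Network

__all__ = [
    "FeatureMatrix",
    "direct_neighbor_counts",
    "second_order_counts",
    "build_feature_matrix",
    "MODES",
]

MODES = ("F1", "F2", "F3")
SECOND_ORDER_RULES = ("distance2", "walks2")


@dataclass(frozen=True)
class FeatureMatrix:
    """N x d feature matrix with a leading all-ones column."""

    values: np.ndarray
    mode: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(v[:, 0] == 1.0):
            raise ValueError("feature column 0 must be all ones")
        if np.any(v < 0):
            raise ValueError("label counts cannot be negative")
        if len(self.columns) != v.shape[1]:
            raise ValueError("column provenance length mismatch")
        object.__setattr__(self, "values", v)

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _labels_of(labels, gene: str) -> float:
    if isinstance(labels, Mapping):
        return float(labels[gene])
    raise TypeError("per-gene operations need a mapping gene -> label")


def direct_neighbor_counts(
    network: Network, labels: Mapping[str, float], gene: str
) -> tuple[int, int]:
    """(label-1 count, label-0 count) over the direct neighbors of ``gene``.

    The gene's own label never enters; an isolated gene yields (0, 0).
    """
    count1 = 0
    count0 = 0
    for nb in network.neighbors(gene):
        if _labels_of(labels, nb) == 1:
            count1 += 1
        else:
            count0 += 1
    return count1, count0


def second_order_counts(
    network: Network,
    labels: Mapping[str, float],
    gene: str,
    rule: str = "distance2",
) -> tuple[int, int]:
    """Label counts over the second-order neighborhood of ``gene``.

    With ``rule="distance2"`` (default) the neighborhood is the set of
    vertices at shortest-path distance exactly 2 — the gene itself and its
    direct neighbors are excluded.  With ``rule="walks2"`` each length-2 walk
    is counted separately (a vertex reachable through several intermediates
    contributes once per intermediate, and direct neighbors may re-enter).
    """
    if rule not in SECOND_ORDER_RULES:
        raise ValueError(f"unknown second-order rule {rule!r}")
    direct = network.neighbors(gene)
    if rule == "distance2":
        ring = set()
        for nb in direct:
            ring.update(network.neighbors(nb))
        ring.discard(gene)
        ring -= direct
        count1 = sum(1 for v in ring if _labels_of(labels, v) == 1)
        return count1, len(ring) - count1
    count1 = 0
    count0 = 0
    for nb in direct:
        for v in network.neighbors(nb):
            if v == gene:
                continue
            if _labels_of(labels, v) == 1:
                count1 += 1
            else:
                count0 += 1
    return count1, count0


def _direct_columns(
    adj: sp.csr_array, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    degree = np.asarray(adj.sum(axis=1)).ravel()
    c1 = adj @ x
    return c1, degree - c1


def counts_from_matrices(
    adj: sp.csr_array, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized label counts: one matrix-vector product per label.

    Works for direct adjacency, distance-2 and walk-2 matrices alike; the
    label-0 count is row-sum minus the label-1 count.
    """
    return _direct_columns(adj, x)


def build_feature_matrix(
    networks: Sequence[Network],
    labels: np.ndarray,
    universe: GeneUniverse,
    mode: str = "F1",
    second_order: str = "distance2",
) -> FeatureMatrix:
    """Assemble the feature matrix for all universe genes in canonical order.

    ``labels`` is the binary prior configuration aligned with
    ``universe.genes``.  F1 and F2 demand exactly one network; F3 accepts
    any positive number, contributing two columns per network in input
    order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    if not networks:
        raise ValueError("at least one network is required")
    x = np.asarray(labels, dtype=float)
    if x.shape != (universe.N,):
        raise ValueError("label vector length does not match universe size")
    if mode in ("F1", "F2") and len(networks) != 1:
        raise ValueError(f"mode {mode} requires exactly one network")

    ones = np.ones(universe.N)
    if mode == "F1":
        c1, c0 = counts_from_matrices(networks[0].adjacency(universe), x)
        values = np.column_stack([ones, c1, c0])
        columns = ("intercept", "direct1", "direct0")
    elif mode == "F2":
        net = networks[0]
        c1, c0 = counts_from_matrices(net.adjacency(universe), x)
        if second_order == "distance2":
            m2 = net.second_order_adjacency(universe)
        else:
            m2 = net.walk2_matrix(universe)
        s1, s0 = counts_from_matrices(m2, x)
        values = np.column_stack([ones, c1, c0, s1, s0])
        columns = ("intercept", "direct1", "direct0", "second1", "second0")
    else:
        parts = [ones]
        columns_list = ["intercept"]
        for j, net in enumerate(networks):
            c1, c0 = counts_from_matrices(net.adjacency(universe), x)
            parts.extend([c1, c0])
            columns_list.extend([f"net{j}_direct1", f"net{j}_direct0"])
        values = np.column_stack(parts)
        columns = tuple(columns_list)
    return FeatureMatrix(values=values, mode=mode, columns=tuple(columns))
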