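"""Shared fixtures: small synthetic instances and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from netlogit import BenchmarkSpec, Dataset, generate_benchmark

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


SMALL_SPEC = BenchmarkSpec(
    n_genes=400,
    n_modules=4,
    module_size=40,
    n_classes=4,
    genes_per_class=10,
    n_complexes=24,
    n_pathways=12,
    n_samples=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_benchmark():
    """400-gene, 4-class benchmark reused across fast tests."""
    return generate_benchmark(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_dataset(small_benchmark):
    b = small_benchmark
    return Dataset.assemble(b.universe, b.networks, b.disease_map, b.complexes)


@pytest.fixture(scope="session")
def single_net_dataset(small_benchmark):
    b = small_benchmark
    return Dataset.assemble(b.universe, b.networks[:1], b.disease_map, b.complexes)


def random_graph_edges(rng: np.random.Generator, n: int, p: float) -> list:
    """Edge list of an Erdos-Renyi draw on vertices v0..v{n-1}."""
    names = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j]))
    return edges


def er_features(
    n: int, avg_degree: float, label_p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-neighbor feature matrix of a large sparse random graph.

    Returns (N x 3 features [1, count1, count0], the binary labels used to
    compute the counts).  Edges are drawn by sampling triangular pair codes,
    which scales to tens of thousands of vertices.
    """
    n_pairs = n * (n - 1) // 2
    m = rng.binomial(n_pairs, avg_degree / (n - 1))
    codes = np.unique(rng.integers(0, n_pairs, size=int(m * 1.05) + 8))[:m]
    # decode triangular index: pair (i, j), i < j
    jj = np.floor((1.0 + np.sqrt(1.0 + 8.0 * codes)) / 2.0).astype(np.int64)
    ii = (codes - jj * (jj - 1) // 2).astype(np.int64)
    adj = sp.csr_array(
        (
            np.ones(2 * len(codes)),
            (np.concatenate([ii, jj]), np.concatenate([jj, ii])),
        ),
        shape=(n, n),
    )
    z = (rng.random(n) < label_p).astype(float)
    c1 = adj @ z
    degree = np.asarray(adj.sum(axis=1)).ravel()
    phi = np.column_stack([np.ones(n), c1, degree - c1])
    return phi, z
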