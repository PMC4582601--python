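"""Self-contained synthetic benchmarks with planted disease modules.

The generator emulates the statistical structure the prioritization method
assumes, so the whole pipeline is testable without any database download:

* genes are partitioned into modules plus a background block, and each
  network is a stochastic block model whose within-module edge probability
  interpolates between the background rate (informativeness 0: edges are
  placed independently of modules) and a planted rate ``p_in``
  (informativeness 1);
* each disease class concentrates its known genes inside one module — the
  "disease genes lie close to each other" property the method exploits;
* protein complexes and pathways are gene sets drawn mostly from single
  modules, so complex-derived priors are informative;
* the expression matrix gives genes of a module a shared latent factor,
  so Pearson correlation above threshold recovers module edges.

Everything derives from one master seed and is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .containers import (
    DiseaseGeneMap,
    ExpressionMatrix,
    GeneSetCollection,
    GeneUniverse,
)
from .networks import Network

__all__ = ["BenchmarkSpec", "Benchmark", "generate_benchmark", "write_fixture", "load_fixture"]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults give a desk-scale analogue of a multi-source disease-gene
    study: 2,000 genes, 12 disease classes of 40 known genes planted in
    12 modules of 80 genes, and three networks of decreasing
    informativeness standing in for a PPI, a pathway co-existence and a
    co-expression data source.
    """

    n_genes: int = 2000
    n_modules: int = 12
    module_size: int = 80
    p_in: float = 0.06
    p_out: float = 0.004
    informativeness: tuple[float, ...] = (1.0, 0.75, 0.5)
    n_classes: int = 12
    genes_per_class: int = 40
    n_complexes: int = 96
    complex_size: tuple[int, int] = (4, 8)
    complex_module_frac: float = 0.9
    n_pathways: int = 36
    pathway_size: tuple[int, int] = (15, 30)
    pathway_module_frac: float = 0.8
    n_samples: int = 40
    within_module_correlation: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes exceed the gene count")
        if self.n_classes > self.n_modules:
            raise ValueError("more disease classes than modules")
        if self.genes_per_class > self.module_size:
            raise ValueError("genes_per_class exceeds module_size")
        if self.genes_per_class < 2:
            raise ValueError("genes_per_class must be >= 2")
        for p in (self.p_in, self.p_out, self.complex_module_frac,
                  self.pathway_module_frac, self.within_module_correlation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.informativeness:
            raise ValueError("at least one network is required")
        for i in self.informativeness:
            if not 0.0 <= i <= 1.0:
                raise ValueError("informativeness must lie in [0, 1]")
        if any(i > 0 for i in self.informativeness) and self.p_in <= self.p_out:
            raise ValueError("informative networks require p_in > p_out")
        if self.n_samples < 3:
            raise ValueError("expression needs >= 3 samples")


@dataclass(frozen=True)
class Benchmark:
    """One generated instance plus its module ground truth."""

    universe: GeneUniverse
    networks: tuple[Network, ...]
    complexes: GeneSetCollection
    pathways: GeneSetCollection
    expression: ExpressionMatrix
    disease_map: DiseaseGeneMap
    module_of: dict = field(default_factory=dict)
    spec: BenchmarkSpec | None = None


def _sbm_edges(
    module_id: np.ndarray, p_within: float, p_between: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Upper-triangle Bernoulli draw with block-dependent probabilities."""
    n = module_id.size
    same = (module_id[:, None] == module_id[None, :]) & (module_id[:, None] >= 0)
    prob = np.where(same, p_within, p_between)
    draw = rng.random((n, n)) < prob
    ii, jj = np.nonzero(np.triu(draw, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def _module_gene_set(
    rng: np.random.Generator,
    module_genes: list[np.ndarray],
    all_genes: np.ndarray,
    size_range: tuple[int, int],
    module_frac: float,
) -> frozenset:
    """Sample one gene set anchored to a random module.

    Each member comes from the anchor module with probability
    ``module_frac`` and from the whole genome otherwise; resampled until at
    least two distinct members remain.
    """
    lo, hi = size_range
    for _ in range(100):
        anchor = int(rng.integers(len(module_genes)))
        size = int(rng.integers(lo, hi + 1))
        from_module = rng.random(size) < module_frac
        members = [
            str(rng.choice(module_genes[anchor]))
            if inside
            else str(rng.choice(all_genes))
            for inside in from_module
        ]
        distinct = frozenset(members)
        if len(distinct) >= 2:
            return distinct
    raise RuntimeError("could not sample a gene set with >= 2 distinct members")


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate one benchmark instance, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = np.array([f"G{i:0{width}d}" for i in range(spec.n_genes)])

    module_id = np.full(spec.n_genes, -1, dtype=int)
    for k in range(spec.n_modules):
        module_id[k * spec.module_size : (k + 1) * spec.module_size] = k
    module_genes = [genes[module_id == k] for k in range(spec.n_modules)]

    networks = []
    for info in spec.informativeness:
        p_within = spec.p_out + info * (spec.p_in - spec.p_out)
        pairs = _sbm_edges(module_id, p_within, spec.p_out, rng)
        edges = [(genes[i], genes[j]) for i, j in pairs]
        networks.append(Network(edges, vertices=genes))

    classes: dict[str, list[str]] = {}
    for k in range(spec.n_classes):
        picked = rng.choice(
            module_genes[k], size=spec.genes_per_class, replace=False
        )
        classes[f"C{k + 1:02d}"] = sorted(str(g) for g in picked)
    disease_map = DiseaseGeneMap(classes)

    complexes = GeneSetCollection(
        {
            f"CPX{i + 1:03d}": _module_gene_set(
                rng, module_genes, genes, spec.complex_size, spec.complex_module_frac
            )
            for i in range(spec.n_complexes)
        }
    )
    pathways = GeneSetCollection(
        {
            f"PWY{i + 1:03d}": _module_gene_set(
                rng, module_genes, genes, spec.pathway_size, spec.pathway_module_frac
            )
            for i in range(spec.n_pathways)
        }
    )

    rho = spec.within_module_correlation
    factors = rng.standard_normal((spec.n_modules, spec.n_samples))
    noise = rng.standard_normal((spec.n_genes, spec.n_samples))
    values = np.sqrt(1.0 - rho) * noise
    in_module = module_id >= 0
    values[in_module] += np.sqrt(rho) * factors[module_id[in_module]]
    expression = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[str(g) for g in genes],
            columns=[f"S{j + 1:03d}" for j in range(spec.n_samples)],
        )
    )

    universe = GeneUniverse.from_known(genes, disease_map.genes())
    return Benchmark(
        universe=universe,
        networks=tuple(networks),
        complexes=complexes,
        pathways=pathways,
        expression=expression,
        disease_map=disease_map,
        module_of={str(g): int(m) for g, m in zip(genes, module_id)},
        spec=spec,
    )


def write_fixture(benchmark: Benchmark, directory: str | PathLike) -> dict[str, Path]:
    """Serialize a benchmark into the tool's on-disk dialects.

    Creates the directory if needed and returns the mapping of artifact
    name to file path.  Reading the files back with :func:`load_fixture`
    reproduces the in-memory benchmark (expression values at 10
    significant digits).
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for j, net in enumerate(benchmark.networks, start=1):
        p = out / f"network_{j}.tsv"
        nio.write_edge_list(p, sorted(net.edges))
        paths[f"network_{j}"] = p
    paths["genes"] = out / "genes.txt"
    nio.write_gene_list(paths["genes"], sorted(benchmark.universe.genes))
    paths["complexes"] = out / "complexes.gmt"
    nio.write_gene_sets(paths["complexes"], benchmark.complexes)
    paths["pathways"] = out / "pathways.gmt"
    nio.write_gene_sets(paths["pathways"], benchmark.pathways)
    paths["associations"] = out / "associations.tsv"
    nio.write_disease_associations(paths["associations"], benchmark.disease_map)
    paths["expression"] = out / "expression.tsv"
    nio.write_expression_matrix(paths["expression"], benchmark.expression)
    return paths


def load_fixture(directory: str | PathLike) -> Benchmark:
    """Read a fixture directory written by :func:`write_fixture`."""
    src = Path(directory)
    genes = nio.read_gene_list(src / "genes.txt")
    disease_map = nio.read_disease_associations(src / "associations.tsv")
    universe = GeneUniverse.from_known(genes, disease_map.genes())
    networks = []
    for p in sorted(src.glob("network_*.tsv"), key=lambda q: int(q.stem.split("_")[1])):
        networks.append(Network(nio.read_edge_list(p), vertices=genes))
    return Benchmark(
        universe=universe,
        networks=tuple(networks),
        complexes=nio.read_gene_sets(src / "complexes.gmt"),
        pathways=nio.read_gene_sets(src / "pathways.gmt"),
        expression=nio.read_expression_matrix(src / "expression.tsv"),
        disease_map=disease_map,
        module_of={},
        spec=None,
    )
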