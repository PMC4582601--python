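"""End-to-end orchestration of the prioritization algorithm.

One disease run executes, in order: prior estimation, prior-label sampling,
feature construction, maximum-likelihood fitting, posterior calculation for
the unknown genes, and percentile decision scoring.  The
:class:`PrioritizationEngine` precomputes everything that does not depend
on the prior configuration — adjacency matrices, second-order matrices and
the complex-membership index — so the leave-one-out protocol (thousands of
re-runs that differ only in labels) stays cheap.

All randomness derives from one master seed; per-disease and per-experiment
generators are derived deterministically from (seed, disease id, gene id),
so a full run is reproducible from a single integer.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, asdict
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from . import io as nio
from .containers import DiseaseGeneMap, GeneSetCollection, GeneUniverse
from .exceptions import DataFormatError, NetlogitError
from .features import MODES, SECOND_ORDER_RULES
from .model import ModelWeights, fit_weights, posterior
from .networks import Network, restrict_to_universe
from .priors import STRATEGIES
from .scoring import DecisionScores, percentile_scores

logger = logging.getLogger("netlogit")

__all__ = [
    "RunConfig",
    "Dataset",
    "PrioritizationEngine",
    "RunResult",
    "run_disease",
    "run_all",
    "derive_rng",
]


def derive_rng(master_seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-context generator from the master seed.

    Tokens (disease ids, gene ids, role tags) are hashed with CRC-32 and
    fed with the master seed into a ``SeedSequence``, so every experiment
    owns an independent, reproducible stream.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode("utf-8")) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of one prioritization run."""

    feature_mode: str = "F3"
    prior_strategy: str = "Pc"
    genome_size: int | None = None
    repeats: int = 1
    seed: int = 0
    second_order: str = "distance2"
    tol: float = 1e-8
    max_iter: int = 500
    weight_cap: float = 50.0
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.feature_mode not in MODES:
            raise ValueError(f"feature_mode must be one of {MODES}")
        if self.prior_strategy not in STRATEGIES:
            raise ValueError(f"prior_strategy must be one of {STRATEGIES}")
        if self.second_order not in SECOND_ORDER_RULES:
            raise ValueError(f"second_order must be one of {SECOND_ORDER_RULES}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.genome_size is not None and self.genome_size < 1:
            raise ValueError("genome_size must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class Dataset:
    """Reconciled inputs: universe, networks, associations and complexes."""

    universe: GeneUniverse
    networks: tuple[Network, ...]
    disease_map: DiseaseGeneMap
    complexes: GeneSetCollection | None = None

    @classmethod
    def assemble(
        cls,
        universe: GeneUniverse,
        networks: Sequence[Network],
        disease_map: DiseaseGeneMap,
        complexes: GeneSetCollection | None = None,
    ) -> "Dataset":
        """Restrict networks to the universe and validate the association map."""
        disease_map.validate_against(universe)
        restricted = tuple(restrict_to_universe(net, universe) for net in networks)
        if not restricted:
            raise DataFormatError("at least one network is required")
        return cls(universe, restricted, disease_map, complexes)


@dataclass(frozen=True)
class RunResult:
    """Decision output for the (effective) unknown genes of one run."""

    unknown_genes: tuple[str, ...]
    posterior: np.ndarray
    score: np.ndarray
    weights: ModelWeights
    n_unknown: int

    def score_of(self, gene: str) -> float:
        return float(self.score[self.unknown_genes.index(gene)])


class PrioritizationEngine:
    """Precomputed state for repeated disease runs on a fixed dataset."""

    def __init__(self, dataset: Dataset, config: RunConfig):
        self.dataset = dataset
        self.config = config
        universe = dataset.universe
        mode = config.feature_mode
        if mode in ("F1", "F2") and len(dataset.networks) != 1:
            raise DataFormatError(
                f"feature mode {mode} requires exactly one network, "
                f"got {len(dataset.networks)}"
            )
        # stack of (matrix, row-sum) pairs; each contributes two feature columns
        stack: list[tuple[sp.csr_array, np.ndarray]] = []
        for net in dataset.networks:
            adj = net.adjacency(universe)
            stack.append((adj, np.asarray(adj.sum(axis=1)).ravel()))
            if mode != "F3":
                break
        if mode == "F2":
            net = dataset.networks[0]
            m2 = (
                net.second_order_adjacency(universe)
                if config.second_order == "distance2"
                else net.walk2_matrix(universe)
            )
            stack.append((m2, np.asarray(m2.sum(axis=1)).ravel()))
        self._stack = stack
        self._d = 1 + 2 * len(stack)
        self._lex = universe.lexicographic_order

        if config.prior_strategy == "Pc":
            if dataset.complexes is None:
                raise DataFormatError("prior strategy Pc requires protein complexes")
            self._membership = self._build_membership(dataset.complexes, universe)
        else:
            self._membership = None

    @staticmethod
    def _build_membership(
        complexes: GeneSetCollection, universe: GeneUniverse
    ) -> tuple[sp.csr_array, np.ndarray, np.ndarray, np.ndarray]:
        """Index complex membership against universe positions.

        Returns (membership CSR over complexes x genes, flat complex ids
        grouped by gene, group start offsets, the genes owning each group).
        """
        rows: list[int] = []
        cols: list[int] = []
        for ci, name in enumerate(complexes):
            for g in complexes[name]:
                if g in universe:
                    rows.append(ci)
                    cols.append(universe.index(g))
        member = sp.csr_array(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(complexes), universe.N),
        )
        cols_arr = np.asarray(cols, dtype=np.int64)
        rows_arr = np.asarray(rows, dtype=np.int64)
        order = np.argsort(cols_arr, kind="stable")
        genes_sorted = cols_arr[order]
        cplx_sorted = rows_arr[order]
        if genes_sorted.size:
            starts = np.flatnonzero(
                np.concatenate(([True], genes_sorted[1:] != genes_sorted[:-1]))
            )
            owners = genes_sorted[starts]
        else:
            starts = np.empty(0, dtype=np.int64)
            owners = np.empty(0, dtype=np.int64)
        return member, cplx_sorted, starts, owners

    # -- per-experiment steps ---------------------------------------------
    def prior_probabilities(
        self, dk_mask: np.ndarray, known_mask: np.ndarray
    ) -> np.ndarray:
        """Prior vector for the effective disease set and known partition."""
        universe = self.dataset.universe
        cfg = self.config
        C = int(dk_mask.sum())
        D = cfg.genome_size if cfg.genome_size is not None else universe.N
        if cfg.prior_strategy == "P0":
            p = np.zeros(universe.N)
        else:
            member, cplx_flat, starts, owners = self._membership
            a = member @ dk_mask.astype(np.float64)
            b = member @ known_mask.astype(np.float64)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(b > 0, a / np.maximum(b, 1.0), -np.inf)
            p = np.full(universe.N, C / D)
            if owners.size:
                gene_max = np.maximum.reduceat(ratio[cplx_flat], starts)
                informative = gene_max > -np.inf
                p[owners[informative]] = gene_max[informative]
        # known genes are fixed regardless of strategy
        p[known_mask] = 0.0
        p[dk_mask] = 1.0
        return p

    def sample_labels(self, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One Bernoulli configuration; uniforms consumed in lex gene order."""
        u = np.empty(p.size)
        u[self._lex] = rng.random(p.size)
        return (u < p).astype(np.float64)

    def feature_matrix(self, x: np.ndarray) -> np.ndarray:
        f = np.empty((x.size, self._d))
        f[:, 0] = 1.0
        for k, (mat, rowsum) in enumerate(self._stack):
            c1 = mat @ x
            f[:, 1 + 2 * k] = c1
            f[:, 2 + 2 * k] = rowsum - c1
        return f

    def run(
        self,
        dk_genes: Iterable[str],
        rng: np.random.Generator,
        demote: str | None = None,
        repeats: int | None = None,
    ) -> RunResult:
        """Execute the full inference + decision pipeline once.

        ``demote`` removes one known gene from both the disease set and the
        known partition for this run (the leave-one-out mechanism), so it is
        scored among the n+1 unknown genes.  With ``repeats`` > 1 the
        label-sampling through scoring steps re-run with fresh draws and the
        per-gene decision scores (and posteriors) are averaged.
        """
        cfg = self.config
        universe = self.dataset.universe
        repeats = cfg.repeats if repeats is None else repeats
        known = universe.known_mask.copy()
        dk_mask = np.zeros(universe.N, dtype=bool)
        for g in dk_genes:
            dk_mask[universe.index(g)] = True
        if demote is not None:
            di = universe.index(demote)
            if not known[di]:
                raise ValueError(f"cannot demote {demote!r}: not a known gene")
            known[di] = False
            dk_mask[di] = False
        if not (dk_mask & known).any():
            logger.warning("disease set empty after demotion; all-zero labels")
        p_prior = self.prior_probabilities(dk_mask & known, known)
        unknown_idx = np.flatnonzero(~known)
        q_acc = np.zeros(unknown_idx.size)
        p_acc = np.zeros(unknown_idx.size)
        weights: ModelWeights | None = None
        for _ in range(repeats):
            x = self.sample_labels(p_prior, rng)
            f = self.feature_matrix(x)
            weights = fit_weights(
                f,
                x,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                weight_cap=cfg.weight_cap,
                ridge=cfg.ridge,
            )
            post = np.asarray(posterior(weights.w, f[unknown_idx]))
            q_acc += percentile_scores(post)
            p_acc += post
        assert weights is not None
        return RunResult(
            unknown_genes=tuple(universe.genes[i] for i in unknown_idx),
            posterior=p_acc / repeats,
            score=q_acc / repeats,
            weights=weights,
            n_unknown=unknown_idx.size,
        )


def run_disease(
    dataset: Dataset, d_k: str, config: RunConfig
) -> DecisionScores:
    """Algorithm steps 1-7 for one disease class: rank its unknown genes."""
    if d_k not in dataset.disease_map:
        raise DataFormatError(f"unknown disease class {d_k!r}")
    engine = PrioritizationEngine(dataset, config)
    return _run_disease_with_engine(engine, d_k)


def _run_disease_with_engine(
    engine: PrioritizationEngine, d_k: str
) -> DecisionScores:
    config = engine.config
    rng = derive_rng(config.seed, d_k, "rank")
    result = engine.run(engine.dataset.disease_map[d_k], rng)
    logger.info(
        "disease %s: w=%s, lnL=%.4f, converged=%s",
        d_k,
        np.array2string(result.weights.w, precision=4),
        result.weights.log_likelihood,
        result.weights.converged,
    )
    return DecisionScores(
        genes=result.unknown_genes,
        posterior=result.posterior,
        score=result.score,
        provenance={
            "disease": d_k,
            "feature_mode": config.feature_mode,
            "prior_strategy": config.prior_strategy,
            "seed": config.seed,
            "weights": result.weights.w.tolist(),
            "log_likelihood": result.weights.log_likelihood,
        },
    )


def run_all(
    dataset: Dataset, config: RunConfig, out_dir: str | PathLike
) -> dict:
    """Rank every disease class; write one ranking file per class + manifest.

    A failing class is logged and skipped; the manifest records successes,
    failures, the config hash and the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    engine = PrioritizationEngine(dataset, config)
    written: dict[str, str] = {}
    failures: dict[str, str] = {}
    for d_k in sorted(dataset.disease_map):
        if not dataset.disease_map[d_k]:
            logger.warning("disease class %r has no genes; skipped", d_k)
            failures[d_k] = "empty class"
            continue
        try:
            scores = _run_disease_with_engine(engine, d_k)
        except NetlogitError as exc:
            logger.error("disease class %r failed: %s", d_k, exc)
            failures[d_k] = str(exc)
            continue
        safe = "".join(c if c.isalnum() or c in "-_." else "_" for c in d_k)
        path = out / f"ranking_{safe}.tsv"
        nio.write_ranking(path, scores.records())
        written[d_k] = path.name
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "master_seed": config.seed,
        "rankings": written,
        "failures": failures,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
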