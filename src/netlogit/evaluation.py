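"""Leave-one-out cross-validation with ROC/AUC evaluation.

For a disease class with s known genes, each known gene is held out in
turn: it is demoted to unknown (dropped from the disease's gene set *and*
from the known partition, so its prior comes from the complex/base-rate
rule like any other candidate), the whole algorithm re-runs, and the
held-out gene's decision score among the n+1 unknown genes is recorded as
a positive-control observation.  floor(s/2) negative controls — known
disease genes of *other* classes, sampled uniformly without replacement —
go through the identical protocol.  The ROC curve sweeps a threshold over
the recorded scores; the AUC is computed by the Mann-Whitney identity
(ties count 1/2), which equals the trapezoidal area under the step ROC.

Both a pooled ROC over all evaluated diseases and per-disease AUCs are
reported, since summaries of multi-disease benchmarks are read both ways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pipeline import Dataset, PrioritizationEngine, RunConfig, derive_rng

logger = logging.getLogger("netlogit")

__all__ = [
    "ValidationResult",
    "mann_whitney_auc",
    "roc_points",
    "roc_auc",
    "select_negative_controls",
    "leave_one_out",
    "evaluate_disease",
    "evaluate_all",
    "permutation_null",
]

RECORD_COLUMNS = ("disease", "gene", "control", "score")


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney U identity; tied scores count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Step ROC from (0,0) to (1,1), thresholding at each observed score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # collapse ties: keep the last cumulative count at each distinct score
    distinct = np.concatenate([s_sorted[1:] != s_sorted[:-1], [True]])
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    return fpr, tpr


@dataclass(frozen=True)
class ValidationResult:
    """Held-out decision scores with control labels, ROC points and AUC."""

    records: pd.DataFrame
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    per_disease: dict[str, float]

    @property
    def n_experiments(self) -> int:
        return len(self.records)


def roc_auc(records: Sequence[tuple[float, bool]] | pd.DataFrame) -> ValidationResult:
    """Assemble a :class:`ValidationResult` from (score, is-positive) records."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(
            {
                "disease": "",
                "gene": [f"r{i}" for i in range(len(records))],
                "control": [
                    "positive" if bool(lab) else "negative" for _, lab in records
                ],
                "score": [float(s) for s, _ in records],
            }
        )
    scores = frame["score"].to_numpy(dtype=float)
    labels = (frame["control"] == "positive").to_numpy()
    fpr, tpr = roc_points(scores, labels)
    auc = mann_whitney_auc(scores, labels)
    per_disease: dict[str, float] = {}
    for d_k, grp in frame.groupby("disease"):
        y = (grp["control"] == "positive").to_numpy()
        if d_k and 0 < y.sum() < y.size:
            per_disease[str(d_k)] = mann_whitney_auc(
                grp["score"].to_numpy(dtype=float), y
            )
    return ValidationResult(
        records=frame.reset_index(drop=True),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        per_disease=per_disease,
    )


def select_negative_controls(
    d_k: str,
    dataset: Dataset,
    s: int,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """floor(s/2) known disease genes not associated with d_k, sampled
    uniformly without replacement (deterministic under a fixed seed)."""
    members = dataset.disease_map[d_k]
    pool = sorted(set(dataset.universe.known_genes()) - set(members))
    want = s // 2
    if len(pool) < want:
        logger.warning(
            "disease %s: negative-control pool (%d) smaller than floor(s/2)=%d; "
            "using the whole pool", d_k, len(pool), want,
        )
        return tuple(pool)
    picked = rng.choice(len(pool), size=want, replace=False)
    return tuple(pool[i] for i in sorted(picked))


def leave_one_out(
    engine: PrioritizationEngine,
    gene: str,
    d_k: str,
    rng: np.random.Generator,
) -> float:
    """Demote ``gene`` to unknown, re-run the algorithm, return its score."""
    dk_genes = engine.dataset.disease_map[d_k]
    result = engine.run(dk_genes, rng, demote=gene)
    return result.score_of(gene)


def evaluate_disease(
    engine: PrioritizationEngine,
    d_k: str,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """All leave-one-out experiments of one disease class.

    Returns the per-experiment record frame (s positives + floor(s/2)
    negatives); a class with fewer than 2 known genes is skipped with a
    warning and yields an empty frame.
    """
    dataset = engine.dataset
    seed = engine.config.seed if master_seed is None else master_seed
    positives = sorted(dataset.disease_map[d_k])
    s = len(positives)
    if s < 2:
        logger.warning("disease %s has %d known gene(s); skipped", d_k, s)
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    negatives = select_negative_controls(
        d_k, dataset, s, derive_rng(seed, d_k, "negatives")
    )
    rows = []
    for gene in positives:
        score = leave_one_out(engine, gene, d_k, derive_rng(seed, d_k, gene))
        rows.append((d_k, gene, "positive", score))
    for gene in negatives:
        score = leave_one_out(engine, gene, d_k, derive_rng(seed, d_k, gene))
        rows.append((d_k, gene, "negative", score))
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def evaluate_all(
    dataset: Dataset,
    config: RunConfig,
    diseases: Sequence[str] | None = None,
) -> ValidationResult:
    """LOOCV over every (or the selected) disease class, pooled into one ROC."""
    engine = PrioritizationEngine(dataset, config)
    targets = sorted(dataset.disease_map) if diseases is None else list(diseases)
    frames = [evaluate_disease(engine, d_k) for d_k in targets]
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(RECORD_COLUMNS)
    )
    if pooled.empty:
        raise ValueError("no evaluable disease class (all have s < 2)")
    return roc_auc(pooled)


def permutation_null(
    records: pd.DataFrame, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """AUCs after shuffling the positive/negative labels of the records.

    Under the null that scores carry no class information the expected AUC
    is 0.5; this is the calibration check for the evaluation protocol.
    """
    scores = records["score"].to_numpy(dtype=float)
    labels = (records["control"] == "positive").to_numpy()
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = mann_whitney_auc(scores, rng.permutation(labels))
    return out
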