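"""Leave-one-out protocol, negative controls and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

from netlogit import (
    Dataset,
    DiseaseGeneMap,
    GeneUniverse,
    PrioritizationEngine,
    RunConfig,
    mann_whitney_auc,
    roc_auc,
)
from netlogit.evaluation import (
    evaluate_disease,
    leave_one_out,
    permutation_null,
    roc_points,
    select_negative_controls,
)
from netlogit.pipeline import derive_rng


def bruteforce_auc(scores, labels):
    """O(P*N) pairwise Mann-Whitney count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_scores_tied(self):
        assert mann_whitney_auc([0.4] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_one_class_empty_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.choice(rng.random(30), size=100)
        labels = rng.random(100) < 0.4
        ours = mann_whitney_auc(scores, labels)
        assert ours == pytest.approx(bruteforce_auc(scores, labels), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_trapezoid_under_step_roc_equals_mann_whitney(self):
        rng = np.random.default_rng(1)
        scores = rng.choice(rng.random(20), size=80)
        labels = rng.random(80) < 0.5
        fpr, tpr = roc_points(scores, labels)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.trapezoid(tpr, fpr) == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        labels = rng.random(60) < 0.5
        assert mann_whitney_auc(np.exp(4 * scores), labels) == pytest.approx(
            mann_whitney_auc(scores, labels)
        )

    def test_per_disease_and_pooled_views(self):
        records = pd.DataFrame(
            {
                "disease": ["D1"] * 4 + ["D2"] * 4,
                "gene": list("abcdefgh"),
                "control": ["positive", "positive", "negative", "negative"] * 2,
                "score": [0.9, 0.8, 0.1, 0.2, 0.6, 0.4, 0.5, 0.3],
            }
        )
        result = roc_auc(records)
        assert result.per_disease["D1"] == 1.0
        assert result.per_disease["D2"] == 0.75
        assert 0.75 <= result.auc <= 1.0


class TestNegativeControls:
    def _dataset(self, small_dataset):
        return small_dataset

    @pytest.mark.parametrize("s, expected", [(10, 5), (7, 3)])
    def test_floor_of_half_s(self, small_dataset, s, expected):
        d_k = sorted(small_dataset.disease_map)[0]
        picked = select_negative_controls(
            d_k, small_dataset, s, np.random.default_rng(0)
        )
        assert len(picked) == expected

    def test_sampled_outside_target_disease_without_replacement(self, small_dataset):
        d_k = sorted(small_dataset.disease_map)[0]
        picked = select_negative_controls(
            d_k, small_dataset, 10, np.random.default_rng(3)
        )
        assert len(set(picked)) == len(picked)
        members = small_dataset.disease_map[d_k]
        known = set(small_dataset.universe.known_genes())
        for g in picked:
            assert g in known and g not in members

    def test_same_seed_identical_sets(self, small_dataset):
        d_k = sorted(small_dataset.disease_map)[0]
        a = select_negative_controls(d_k, small_dataset, 8, np.random.default_rng(9))
        b = select_negative_controls(d_k, small_dataset, 8, np.random.default_rng(9))
        assert a == b

    def test_small_pool_taken_whole_with_warning(self, caplog):
        universe = GeneUniverse.from_known(list("abcdefgh"), list("efgh"))
        dmap = DiseaseGeneMap({"D1": ["e", "f", "g"], "D2": ["h"]})
        from netlogit.networks import Network

        ds = Dataset.assemble(universe, [Network([("a", "b")])], dmap)
        with caplog.at_level("WARNING", logger="netlogit"):
            picked = select_negative_controls("D1", ds, 10, np.random.default_rng(0))
        assert picked == ("h",) and "pool" in caplog.text


class TestLeaveOneOutProtocol:
    def test_experiment_count_is_s_plus_floor_half_s(self, small_dataset):
        engine = PrioritizationEngine(
            small_dataset, RunConfig(feature_mode="F3", prior_strategy="P0", seed=5)
        )
        d_k = sorted(small_dataset.disease_map)[0]
        s = len(small_dataset.disease_map[d_k])
        frame = evaluate_disease(engine, d_k)
        assert len(frame) == s + s // 2
        assert (frame["control"] == "positive").sum() == s

    def test_held_out_gene_scored_among_n_plus_one_unknowns(self, small_dataset):
        engine = PrioritizationEngine(small_dataset, RunConfig(seed=5))
        d_k = sorted(small_dataset.disease_map)[0]
        gene = sorted(small_dataset.disease_map[d_k])[0]
        result = engine.run(
            small_dataset.disease_map[d_k], derive_rng(5, d_k, gene), demote=gene
        )
        assert result.n_unknown == small_dataset.universe.n + 1
        assert gene in result.unknown_genes

    def test_skips_class_with_single_gene(self, small_dataset, caplog):
        dmap = DiseaseGeneMap(
            dict(small_dataset.disease_map) | {"TINY": [next(iter(small_dataset.disease_map["C01"]))]}
        )
        ds = Dataset(
            small_dataset.universe,
            small_dataset.networks,
            dmap,
            small_dataset.complexes,
        )
        engine = PrioritizationEngine(
            Dataset(ds.universe, ds.networks[:1], ds.disease_map, ds.complexes),
            RunConfig(seed=1, prior_strategy="P0", feature_mode="F1"),
        )
        with caplog.at_level("WARNING", logger="netlogit"):
            frame = evaluate_disease(engine, "TINY")
        assert frame.empty and "skipped" in caplog.text

    def test_no_leakage_of_heldout_membership(self, small_benchmark):
        """Demoting g equals deleting g's disease membership from the inputs."""
        b = small_benchmark
        d_k = sorted(b.disease_map)[0]
        gene = sorted(b.disease_map[d_k])[0]
        config = RunConfig(feature_mode="F3", prior_strategy="Pc", seed=17)

        ds1 = Dataset.assemble(b.universe, b.networks, b.disease_map, b.complexes)
        engine1 = PrioritizationEngine(ds1, config)
        score1 = leave_one_out(engine1, gene, d_k, derive_rng(17, d_k, gene))

        # rebuild the world as if g had never been associated with any disease
        stripped = DiseaseGeneMap(
            {k: set(v) - {gene} for k, v in b.disease_map.items()}
        )
        universe2 = GeneUniverse.from_known(b.universe.genes, stripped.genes())
        ds2 = Dataset.assemble(universe2, b.networks, stripped, b.complexes)
        engine2 = PrioritizationEngine(ds2, config)
        result2 = engine2.run(stripped[d_k], derive_rng(17, d_k, gene))
        assert result2.score_of(gene) == score1

    def test_permutation_null_centers_on_half(self, small_dataset):
        engine = PrioritizationEngine(
            small_dataset, RunConfig(feature_mode="F3", prior_strategy="P0", seed=2)
        )
        d_k = sorted(small_dataset.disease_map)[0]
        records = evaluate_disease(engine, d_k)
        aucs = permutation_null(records, 30, np.random.default_rng(0))
        assert abs(aucs.mean() - 0.5) < 0.1

    def test_isolated_gene_gets_shared_intercept_only_score(self):
        """A gene with no edges anywhere shares the intercept-only posterior."""
        from netlogit.networks import Network

        unknown = [f"u{i}" for i in range(6)]
        known = ["k1", "k2", "k3", "k4"]
        universe = GeneUniverse.from_known(unknown + known, known)
        # u0 and u1 isolated; others wired to knowns
        net = Network(
            [("u2", "k1"), ("u3", "k2"), ("u4", "k1"), ("u5", "k3"), ("k1", "k2")],
            vertices=universe.genes,
        )
        dmap = DiseaseGeneMap({"D1": ["k1", "k2"], "D2": ["k3", "k4"]})
        ds = Dataset.assemble(universe, [net], dmap)
        engine = PrioritizationEngine(
            ds, RunConfig(feature_mode="F1", prior_strategy="P0", seed=0)
        )
        result = engine.run(dmap["D1"], derive_rng(0, "D1", "rank"))
        i0 = result.unknown_genes.index("u0")
        i1 = result.unknown_genes.index("u1")
        assert result.posterior[i0] == result.posterior[i1]
        assert result.score[i0] == result.score[i1]
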