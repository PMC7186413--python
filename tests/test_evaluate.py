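"""Label assembly, metrics, cross-validation and leakage control."""

import numpy as np
import pytest

from netgene.evaluate import (
    ClassifierSpec,
    LabelSet,
    MetricsReport,
    assemble_labels,
    compute_metrics,
    cross_validate,
    cross_validate_baseline,
)
from netgene.graph import Graph
from netgene.synth import generate_feature_blobs

from conftest import random_graph
from oracles import auprc_sweep, auroc_pairs


class TestAssembleLabels:
    @pytest.fixture
    def graph1000(self):
        return random_graph(200, 0.05, seed=0)

    def test_balanced_and_disjoint(self, graph1000):
        disease = {f"n{i}" for i in range(50)}
        ls = assemble_labels(graph1000, disease, seed=1)
        assert ls.n_samples == 100
        assert (ls.labels == 1).sum() == 50
        assert set(ls.positives()).isdisjoint(set(ls.negatives()))

    def test_determinism(self, graph1000):
        disease = {f"n{i}" for i in range(30)}
        a = assemble_labels(graph1000, disease, seed=7)
        b = assemble_labels(graph1000, disease, seed=7)
        assert np.array_equal(a.negatives(), b.negatives())

    def test_disjoint_disease_set_is_error(self, graph1000):
        with pytest.raises(ValueError):
            assemble_labels(graph1000, {"absent1", "absent2"}, seed=0)

    def test_missing_genes_reported(self, graph1000):
        ls = assemble_labels(graph1000, {"n0", "n1", "ghost"}, seed=0)
        assert ls.missing_genes == ["ghost"]

    def test_insufficient_negatives_is_error(self):
        g = Graph.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        with pytest.raises(ValueError):
            assemble_labels(g, {"a", "b"}, seed=0)

    def test_unbalanced_construction_rejected(self):
        with pytest.raises(ValueError):
            LabelSet(gene_indices=np.array([0, 1, 2]),
                     labels=np.array([1, 1, 0]), seed=0)


class TestComputeMetrics:
    def test_worked_auroc_case(self):
        """scores (0.9, 0.8, 0.4, 0.3), labels (1,0,1,0): 3 of 4
        positive-negative pairs are concordant -> AUROC 0.75."""
        m = compute_metrics(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 0, 1, 0]))
        assert m.auroc == 0.75

    def test_perfect_separation(self):
        m = compute_metrics(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m.auroc == 1.0 and m.auprc == 1.0

    def test_all_ties_give_half(self):
        m = compute_metrics(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert m.auroc == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0.1, 0.2]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        m = compute_metrics(scores, labels)
        assert abs(m.auroc - auroc_pairs(scores, labels)) < 1e-10
        assert abs(m.auprc - auprc_sweep(scores, labels)) < 1e-10


def _blob_labelset(n_per_class):
    idx = np.arange(2 * n_per_class)
    labels = np.concatenate([np.zeros(n_per_class, dtype=int),
                             np.ones(n_per_class, dtype=int)])
    return LabelSet(gene_indices=idx, labels=labels, seed=0)


class TestCrossValidate:
    def test_partition_covers_each_sample_once(self):
        X, y = generate_feature_blobs(30, 4, separation=2.0, seed=0)
        ls = _blob_labelset(30)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = np.concatenate([te for _, te in skf.split(X, y)])
        assert sorted(seen.tolist()) == list(range(60))

    @pytest.mark.parametrize("kind", ["svm_rbf", "logistic", "random_forest"])
    def test_separable_blobs_reach_high_auroc(self, kind):
        """Two Gaussian classes 6 sigma apart are Bayes-separable; every
        classifier should reach near-perfect ranking."""
        X, y = generate_feature_blobs(100, 2, separation=6.0, seed=1)
        rep = cross_validate(X, _blob_labelset(100), ClassifierSpec(kind=kind), seed=2)
        assert rep.mean().auroc >= 0.99

    def test_mean_std_match_recomputation(self):
        X, y = generate_feature_blobs(40, 2, separation=1.0, seed=2)
        rep = cross_validate(X, _blob_labelset(40), ClassifierSpec(kind="logistic"), seed=0)
        vals = np.array([m.auroc for m in rep.fold_metrics])
        assert np.isclose(rep.mean().auroc, vals.mean())
        assert np.isclose(rep.std().auroc, vals.std())
        assert rep.n_folds == 5

    def test_sample_order_permutation_invariance(self):
        X, _ = generate_feature_blobs(40, 3, separation=2.0, seed=3)
        ls = _blob_labelset(40)
        rep = cross_validate(X, ls, ClassifierSpec(kind="logistic"), seed=5)
        perm = np.random.default_rng(0).permutation(80)
        ls_p = LabelSet(gene_indices=ls.gene_indices[perm], labels=ls.labels[perm], seed=0)
        rep_p = cross_validate(X[perm], ls_p, ClassifierSpec(kind="logistic"), seed=5)
        assert rep.to_dict()["mean"] == rep_p.to_dict()["mean"]

    def test_determinism(self):
        X, _ = generate_feature_blobs(30, 3, separation=1.5, seed=4)
        ls = _blob_labelset(30)
        a = cross_validate(X, ls, ClassifierSpec(kind="svm_rbf"), seed=6)
        b = cross_validate(X, ls, ClassifierSpec(kind="svm_rbf"), seed=6)
        assert a.to_dict() == b.to_dict()

    def test_fewer_samples_than_folds_is_error(self):
        ls = _blob_labelset(2)
        with pytest.raises(ValueError):
            cross_validate(np.zeros((4, 2)), ls, ClassifierSpec(), folds=5)

    def test_reducer_is_fit_per_fold_on_training_rows_only(self):
        X, _ = generate_feature_blobs(25, 4, separation=2.0, seed=5)
        ls = _blob_labelset(25)
        seen_sizes = []

        def factory(train_X, seed):
            seen_sizes.append(train_X.shape[0])
            return lambda Z: Z

        cross_validate(X, ls, ClassifierSpec(kind="logistic"), seed=0,
                       reducer_factory=factory)
        assert len(seen_sizes) == 5
        assert all(s == 40 for s in seen_sizes)  # 80% of 50


class TestBaselineCV:
    def test_planted_module_rwr_beats_chance(self):
        from netgene.synth import SynthConfig, generate_benchmark

        graph, disease = generate_benchmark(
            SynthConfig(n_nodes=300, module_size=30, intra_module_prob=0.4,
                        isolated_fraction=0.0, seed=2)
        )
        ls = assemble_labels(graph, disease, seed=3)
        rep = cross_validate_baseline(graph, ls, "rwr", seed=4)
        assert rep.mean().auroc > 0.6
        stacked = np.asarray(rep.fold_metrics)
        assert np.all((stacked >= 0) & (stacked <= 1))

    def test_unknown_method_rejected(self, triangle):
        ls = LabelSet(gene_indices=np.array([0, 1]), labels=np.array([1, 0]), seed=0)
        with pytest.raises(ValueError):
            cross_validate_baseline(triangle, ls, "pagerank")


def test_report_serialization_shapes(tmp_path):
    from netgene.evaluate import Metrics

    rep = MetricsReport(config="demo", fold_metrics=[
        Metrics(0.8, 0.7, 0.9, 0.85), Metrics(0.6, 0.5, 0.7, 0.65)])
    rows = rep.tsv_rows().strip().split("\n")
    assert [r.split("\t")[0] for r in rows] == ["accuracy", "f1", "auroc", "auprc"]
    p = tmp_path / "r.json"
    rep.to_json(p)
    import json

    d = json.loads(p.read_text())
    assert d["mean"]["auroc"] == pytest.approx(0.8)
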