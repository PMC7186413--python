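"""Label assembly, classifiers, cross-validation and metrics.

Positives are the disease genes present in the graph; negatives are
sampled uniformly without replacement from the remaining nodes, equal
in number (balanced by construction).  Evaluation is stratified k-fold
cross-validation (5 folds, i.e. 80/20 splits) reporting accuracy, F1,
AUROC and AUPRC per fold and as mean +/- fold-wise std.

Classifier fitting, grid search and metric computation go through
scikit-learn.  All leakage-sensitive steps — feature standardization,
SVM grid search, optional autoencoder reduction, baseline seed sets —
see training-fold data only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import baselines as _baselines
from .embedding import Embedding
from .graph import Graph
from .line import LineConfig, train_line
from .sae import SAEConfig, encode, train_sae
from .seeding import child_seed
from .skipgram import SkipGramConfig, train_skipgram
from .walks import WalkConfig, generate_walks

__all__ = [
    "LabelSet",
    "ClassifierSpec",
    "EmbedderSpec",
    "Metrics",
    "MetricsReport",
    "assemble_labels",
    "compute_metrics",
    "cross_validate",
    "cross_validate_baseline",
    "embed_graph",
    "run_pipeline",
    "benchmark_table",
]


# ---------------------------------------------------------------------------
# labels


@dataclass
class LabelSet:
    """Balanced (gene, label) samples with negative-sampling provenance."""

    gene_indices: np.ndarray  # (n_samples,)
    labels: np.ndarray        # (n_samples,) in {0, 1}
    seed: int
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.gene_indices.size != self.labels.size:
            raise ValueError("gene_indices and labels length mismatch")
        if (self.labels == 1).sum() != (self.labels == 0).sum():
            raise ValueError("LabelSet must be balanced")
        if np.unique(self.gene_indices).size != self.gene_indices.size:
            raise ValueError("a gene appears twice in the LabelSet")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def positives(self) -> np.ndarray:
        return self.gene_indices[self.labels == 1]

    def negatives(self) -> np.ndarray:
        return self.gene_indices[self.labels == 0]


def assemble_labels(graph: Graph, disease_genes, seed: int) -> LabelSet:
    """Balanced positive/negative gene labels.

    Positives: disease genes present in the graph (graph index order).
    Negatives: an equal number of the remaining nodes, sampled uniformly
    without replacement with the given seed.  Disease genes absent from
    the graph are reported on the LabelSet, not silently dropped.
    """
    disease = set(disease_genes)
    pos = np.asarray(sorted(graph.index[g] for g in disease if g in graph.index),
                     dtype=np.int64)
    missing = sorted(g for g in disease if g not in graph.index)
    if pos.size == 0:
        raise ValueError("no disease gene is present in the graph")
    pool = np.setdiff1d(np.arange(graph.n_nodes, dtype=np.int64), pos)
    if pool.size < pos.size:
        raise ValueError(
            f"cannot draw {pos.size} negatives from {pool.size} non-disease genes"
        )
    rng = np.random.default_rng(seed)
    neg = np.sort(rng.choice(pool, size=pos.size, replace=False))
    return LabelSet(
        gene_indices=np.concatenate([pos, neg]),
        labels=np.concatenate([np.ones(pos.size, dtype=np.int64),
                               np.zeros(neg.size, dtype=np.int64)]),
        seed=seed,
        missing_genes=missing,
    )


# ---------------------------------------------------------------------------
# metrics


class Metrics(NamedTuple):
    accuracy: float
    f1: float
    auroc: float
    auprc: float


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    predictions: np.ndarray | None = None,
    threshold: float = 0.5,
) -> Metrics:
    """Accuracy, F1, AUROC (ties count 1/2) and AUPRC (step-wise PR sum).

    ``scores`` are continuous ranking scores; hard ``predictions`` for
    accuracy/F1 default to thresholding the scores at ``threshold``
    (appropriate for calibrated probabilities — classifiers pass their
    own decision-rule predictions instead).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size != labels.size:
        raise ValueError("scores and labels length mismatch")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    if predictions is None:
        predictions = (scores >= threshold).astype(np.int64)
    return Metrics(
        accuracy=float(accuracy_score(labels, predictions)),
        f1=float(f1_score(labels, predictions, zero_division=0)),
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
    )


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics for one configuration."""

    config: str
    fold_metrics: list[Metrics]

    def _stack(self) -> np.ndarray:
        return np.asarray(self.fold_metrics, dtype=np.float64)  # (folds, 4)

    def mean(self) -> Metrics:
        return Metrics(*self._stack().mean(axis=0))

    def std(self) -> Metrics:
        return Metrics(*self._stack().std(axis=0))

    @property
    def n_folds(self) -> int:
        return len(self.fold_metrics)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "folds": [m._asdict() for m in self.fold_metrics],
            "mean": self.mean()._asdict(),
            "std": self.std()._asdict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def tsv_rows(self) -> str:
        """One ``metric<TAB>mean<TAB>std`` line per metric."""
        m, s = self.mean(), self.std()
        return "".join(
            f"{name}\t{mv:.4f}\t{sv:.4f}\n"
            for name, mv, sv in zip(Metrics._fields, m, s)
        )

    def summary(self) -> str:
        """Table-style cells ``mean (std)`` for the four metrics."""
        m, s = self.mean(), self.std()
        cells = "\t".join(f"{mv:.4f} ({sv:.4f})" for mv, sv in zip(m, s))
        return f"{self.config}\t{cells}"


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierSpec:
    """Classifier choice and its (fixed, reproducible) hyperparameters.

    The SVM grid C x gamma is searched by inner stratified CV on AUROC;
    "scale" denotes scikit-learn's 1/(d * Var[x]) kernel-width heuristic.
    """

    kind: str = "svm_rbf"  # {"svm_rbf", "logistic", "random_forest"}
    svm_C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, "scale")
    inner_folds: int = 3
    rf_n_estimators: int = 500
    logistic_C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "logistic", "random_forest"):
            raise ValueError(f"unknown classifier {self.kind!r}")
        if self.kind == "svm_rbf" and (not self.svm_C_grid or not self.svm_gamma_grid):
            raise ValueError("empty SVM grid")


def _build_estimator(spec: ClassifierSpec, seed: int):
    if spec.kind == "svm_rbf":
        pipe = Pipeline([("scale", StandardScaler()), ("clf", SVC(kernel="rbf"))])
        return GridSearchCV(
            pipe,
            param_grid={
                "clf__C": list(spec.svm_C_grid),
                "clf__gamma": list(spec.svm_gamma_grid),
            },
            cv=StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                               random_state=seed),
            scoring="roc_auc",
            n_jobs=1,
        )
    if spec.kind == "logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=spec.logistic_C, max_iter=2000)),
        ])
    return RandomForestClassifier(n_estimators=spec.rf_n_estimators,
                                  random_state=seed, n_jobs=1)


def _ranking_scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=np.float64)
    return np.asarray(estimator.predict_proba(X)[:, 1], dtype=np.float64)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    features: np.ndarray,
    labelset: LabelSet,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = 0,
    reducer_factory: Callable[[np.ndarray, int], Callable[[np.ndarray], np.ndarray]] | None = None,
    config_name: str | None = None,
) -> MetricsReport:
    """Stratified k-fold evaluation of one feature/classifier configuration.

    ``features`` rows align with ``labelset`` samples.  An optional
    ``reducer_factory(train_X, seed) -> transform`` (e.g. an autoencoder
    fit) is refit inside every fold on training rows only.  Samples are
    put in canonical gene-index order before fold assignment, so the
    report does not depend on how the rows were permuted.
    """
    X = np.asarray(features, dtype=np.float64)
    y = labelset.labels
    if X.shape[0] != y.size:
        raise ValueError("features are not row-aligned with the label set")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if y.size < folds:
        raise ValueError("fewer samples than folds")
    canon = np.argsort(labelset.gene_indices, kind="stable")
    X, y = X[canon], y[canon]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[Metrics] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_seed = child_seed(seed, "fold", fold)
        X_tr, X_te = X[tr], X[te]
        if reducer_factory is not None:
            transform = reducer_factory(X_tr, fold_seed)
            X_tr, X_te = transform(X_tr), transform(X_te)
        est = _build_estimator(spec, fold_seed)
        est.fit(X_tr, y[tr])
        fold_metrics.append(
            compute_metrics(
                _ranking_scores(est, X_te), y[te], predictions=est.predict(X_te)
            )
        )
    return MetricsReport(config=config_name or spec.kind, fold_metrics=fold_metrics)


_BASELINE_SCORERS = {
    "rwr": _baselines.rwr_scores,
    "spl": _baselines.spl_scores,
    "ed": _baselines.ed_scores,
}


def cross_validate_baseline(
    graph: Graph,
    labelset: LabelSet,
    method: str,
    folds: int = 5,
    seed: int = 0,
    **scorer_kwargs,
) -> MetricsReport:
    """Evaluate a graph-proximity baseline under the classifier protocol.

    Within each fold the seed set is the training-fold positives only
    (test positives are withheld to avoid label leakage).  AUROC/AUPRC
    use the raw proximity scores; accuracy/F1 come from a one-feature
    logistic model fit on the training-fold scores, since proximity
    scores carry no natural decision threshold.

    Two details make that threshold meaningful.  Each training
    positive's own score is computed leave-one-out (itself removed from
    the seed set): a seed's score is otherwise inflated by its restart
    or zero-distance mass and never resembles the held-out positives
    the threshold must generalize to.  And the logistic is effectively
    unregularized (large C): diffusion scores span orders of magnitude,
    so after standardization the separating gap can be tiny relative to
    hub-driven outliers and a penalized fit would collapse to majority
    prediction.
    """
    if method not in _BASELINE_SCORERS:
        raise ValueError(f"unknown baseline {method!r}")
    scorer = _BASELINE_SCORERS[method]
    canon = np.argsort(labelset.gene_indices, kind="stable")
    genes, y = labelset.gene_indices[canon], labelset.labels[canon]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: list[Metrics] = []
    for tr, te in skf.split(genes, y):
        train_pos = genes[tr][y[tr] == 1]
        seed_genes = {graph.nodes[i] for i in train_pos}
        sv = scorer(graph, seed_genes, **scorer_kwargs)
        s = sv.scores[genes]
        # leave-one-out scores for the training positives themselves
        s_train = s[tr].copy()
        for row, gi in enumerate(genes[tr]):
            if y[tr][row] == 1:
                loo = scorer(graph, seed_genes - {graph.nodes[gi]}, **scorer_kwargs)
                s_train[row] = loo.scores[gi]
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1e6, max_iter=5000)),
        ])
        clf.fit(s_train[:, None], y[tr])
        fold_metrics.append(
            compute_metrics(s[te], y[te], predictions=clf.predict(s[te, None]))
        )
    return MetricsReport(config=method.upper(), fold_metrics=fold_metrics)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class EmbedderSpec:
    """Which network-representation-learning method to run, and how."""

    method: str = "node2vec"  # {"deepwalk", "node2vec", "line"}
    dim: int = 128
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    epochs: int = 5
    negatives: int = 5
    line_order: str = "concat-both"
    line_total_samples: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("deepwalk", "node2vec", "line"):
            raise ValueError(f"unknown embedding method {self.method!r}")


def embed_graph(graph: Graph, spec: EmbedderSpec, seed: int) -> Embedding:
    """Run the configured embedding method on the whole graph."""
    if spec.method == "line":
        return train_line(
            graph,
            LineConfig(
                dim=spec.dim,
                order=spec.line_order,
                total_samples=spec.line_total_samples,
                negatives=spec.negatives,
                seed=child_seed(seed, "line"),
            ),
        )
    walk_cfg = WalkConfig(
        walks_per_node=spec.walks_per_node,
        walk_length=spec.walk_length,
        strategy=spec.method,
        p=spec.p,
        q=spec.q,
        seed=child_seed(seed, "walks"),
    )
    corpus = generate_walks(graph, walk_cfg)
    sg_cfg = SkipGramConfig(
        dim=spec.dim,
        window=spec.window,
        epochs=spec.epochs,
        negatives=spec.negatives,
        seed=child_seed(seed, "skipgram"),
    )
    return train_skipgram(corpus, graph, sg_cfg)


def _sae_reducer_factory(sae_dims: list[int], epochs: int = 100):
    def factory(train_X: np.ndarray, seed: int):
        cfg = SAEConfig(layer_dims=list(sae_dims), epochs=epochs, seed=seed)
        model = train_sae(train_X, cfg)
        return lambda X: encode(model, X)

    return factory


def run_pipeline(
    graph: Graph,
    disease_genes,
    embedder: EmbedderSpec,
    sae_dims: list[int] | None,
    classifier: ClassifierSpec,
    seed: int = 0,
    folds: int = 5,
    sae_epochs: int = 100,
    embedding: Embedding | None = None,
) -> MetricsReport:
    """Embed -> (optionally) autoencode -> classify, under k-fold CV.

    The graph is embedded once; the autoencoder, feature scaling and
    grid search are refit per fold on training rows only.  A
    precomputed ``embedding`` may be passed to share one embedding
    across several configurations.
    """
    emb = embedding if embedding is not None else embed_graph(
        graph, embedder, child_seed(seed, "embed")
    )
    if sae_dims is not None and sae_dims[0] != emb.dim:
        raise ValueError(
            f"autoencoder input width {sae_dims[0]} != embedding dim {emb.dim}"
        )
    labelset = assemble_labels(graph, disease_genes, child_seed(seed, "labels"))
    features = emb.rows(labelset.gene_indices)
    reducer = _sae_reducer_factory(sae_dims, sae_epochs) if sae_dims is not None else None
    name = embedder.method + ("-SAE" if sae_dims is not None else "") + f"-{classifier.kind}"
    return cross_validate(
        features, labelset, classifier,
        folds=folds, seed=child_seed(seed, "cv"),
        reducer_factory=reducer, config_name=name,
    )


def benchmark_table(
    graph: Graph,
    disease_genes,
    dim: int = 128,
    sae_dims: list[int] | None = None,
    seed: int = 0,
    folds: int = 5,
    sae_epochs: int = 100,
    embedder_overrides: dict | None = None,
) -> list[MetricsReport]:
    """The six-configuration comparison: ED, SPL, RWR, and the three
    embedding pipelines, all sharing one LabelSet and fold assignment.

    ``sae_dims`` defaults to ``[dim, 64]`` compression for the
    embedding rows.
    """
    if sae_dims is None:
        sae_dims = [dim, 64] if dim > 64 else [dim, max(2, dim // 2)]
    label_seed = child_seed(seed, "labels")
    cv_seed = child_seed(seed, "cv")
    labelset = assemble_labels(graph, disease_genes, label_seed)

    reports: list[MetricsReport] = []
    for method in ("ed", "spl", "rwr"):
        reports.append(
            cross_validate_baseline(graph, labelset, method, folds=folds, seed=cv_seed)
        )
    overrides = embedder_overrides or {}
    for method in ("line", "node2vec", "deepwalk"):
        espec = EmbedderSpec(method=method, dim=dim, **overrides.get(method, {}))
        emb = embed_graph(graph, espec, child_seed(seed, f"embed:{method}"))
        features = emb.rows(labelset.gene_indices)
        rep = cross_validate(
            features, labelset, ClassifierSpec(kind="svm_rbf"),
            folds=folds, seed=cv_seed,
            reducer_factory=_sae_reducer_factory(sae_dims, sae_epochs),
            config_name={"line": "LINE", "node2vec": "node2vec",
                         "deepwalk": "DeepWalk"}[method] + "-SAE-SVM",
        )
        reports.append(rep)
    return reports
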