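"""Classifier training on enrichment-table features against MAE/BAE labels.

A roster of nine algorithm families is trained with stratified k-fold
cross-validation; within each family, hyperparameters are chosen to
maximize the mean Cohen's kappa across folds. Kappa, rather than accuracy,
is the objective because MAE genes are a 5-20% minority and accuracy is
dominated by the majority class. A final model is refit on all training
data with the selected hyperparameters, and a per-model summary (CV-mean
precision/recall/F1/kappa/accuracy) is emitted; the model with the best F1
is selected by default downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import BAE, MAE, ConfusionMatrix, PerformanceMetrics, metrics

__all__ = [
    "TrainedModel",
    "ModelRegistry",
    "default_registry",
    "read_labels",
    "join_features_labels",
    "train_all",
    "select_best",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "chromae-model-1"


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a labels TSV with header ``gene_id<TAB>status``, status MAE|BAE."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "status"} <= set(df.columns):
        raise ValueError(f"{path}: labels file needs gene_id and status columns")
    labels: dict[str, str] = {}
    for gene_id, status in zip(df["gene_id"], df["status"]):
        if status not in (MAE, BAE):
            raise ValueError(
                f"{path}: gene {gene_id} has unknown status {status!r} "
                f"(expected {MAE} or {BAE})"
            )
        if gene_id in labels:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        labels[str(gene_id)] = status
    return labels


def join_features_labels(
    table: pd.DataFrame, labels: dict[str, str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Inner-join the enrichment table with the label set.

    Returns the feature matrix (rows = labeled genes present in the table)
    and the class vector; genes present in only one input are dropped and
    counted in the log. MAE is the positive class throughout.
    """
    for gene, status in labels.items():
        if status not in (MAE, BAE):
            raise ValueError(f"gene {gene}: unknown status {status!r}")
    common = [g for g in table.index if g in labels]
    if not common:
        raise ValueError("no genes shared between enrichment table and labels")
    n_table_only = len(table.index) - len(common)
    n_labels_only = len(labels) - len(common)
    if n_table_only or n_labels_only:
        logger.info(
            "join dropped %d table-only and %d label-only genes",
            n_table_only, n_labels_only,
        )
    X = table.loc[common]
    y = np.array([labels[g] for g in common])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both MAE and BAE examples")
    return X, y


# ---------------------------------------------------------------------------
# model registry


class ColumnSubset(BaseEstimator, TransformerMixin):
    """Select a subset of feature columns by index (for stepwise glm)."""

    def __init__(self, indices: tuple[int, ...] = ()):
        self.indices = indices

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, list(self.indices)]


@dataclass
class AlgorithmSpec:
    """One registry entry: a named family with a candidate pool to tune over."""

    name: str
    build_candidates: "callable"  # (n_features, seed) -> list[estimator]

    def candidates(self, n_features: int, seed: int):
        return self.build_candidates(n_features, seed)


def _glm_candidates(n_features: int, seed: int):
    # best-subset feature selection over all non-empty subsets, crossed with
    # a small regularization grid; exact stepwise at this dimensionality
    cands = []
    subsets = [
        s for r in range(1, n_features + 1)
        for s in combinations(range(n_features), r)
    ]
    for subset in subsets:
        for C in (0.1, 1.0, 10.0):
            cands.append(Pipeline([
                ("subset", ColumnSubset(subset)),
                ("clf", LogisticRegression(C=C, solver="lbfgs", max_iter=1000)),
            ]))
    return cands


def _svm_candidates(n_features, seed):
    # no probability=True: SVMs have no native class probability, and the
    # score column is only emitted for families that do
    return [
        SVC(kernel=kernel, C=C, gamma="scale", random_state=seed)
        for kernel in ("linear", "rbf")
        for C in (0.5, 2.0, 8.0)
    ]


def _nnet_candidates(n_features, seed):
    # fixed two-hidden-layer network; tune only the weight penalty.
    # lbfgs converges reliably on small, low-dimensional designs
    return [
        MLPClassifier(hidden_layer_sizes=(8, 8), alpha=alpha, solver="lbfgs",
                      max_iter=2000, random_state=seed)
        for alpha in (1e-4, 1e-2)
    ]


def _mlp_candidates(n_features, seed):
    return [
        MLPClassifier(hidden_layer_sizes=size, alpha=1e-4, solver="lbfgs",
                      max_iter=2000, random_state=seed)
        for size in ((4,), (16,))
    ]


def _rf_candidates(n_features, seed):
    return [
        RandomForestClassifier(n_estimators=200, min_samples_leaf=leaf,
                               random_state=seed)
        for leaf in (1, 5)
    ]


def _knn_candidates(n_features, seed):
    return [KNeighborsClassifier(n_neighbors=k) for k in (5, 11, 21)]


def _ada_candidates(n_features, seed):
    return [
        AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth),
            n_estimators=n, random_state=seed,
        )
        for depth in (1, 2)
        for n in (50,)
    ]


def _rpart_candidates(n_features, seed):
    return [
        DecisionTreeClassifier(max_depth=depth, min_samples_leaf=leaf,
                               random_state=seed)
        for depth in (2, 4, 8)
        for leaf in (1, 10)
    ]


class GeneticTreeSpec(AlgorithmSpec):
    """Decision tree with hyperparameters evolved by a small genetic algorithm.

    The GA (population 10, 4 generations, tournament selection, per-gene
    mutation) searches (max_depth, min_samples_leaf, criterion) for the
    candidate maximizing mean CV kappa; the search is fully seeded.
    """

    POP, GENERATIONS = 10, 4
    DEPTHS = list(range(1, 9))
    LEAVES = [1, 2, 5, 10, 20]
    CRITERIA = ["gini", "entropy"]

    def __init__(self):
        super().__init__(name="ga_tree", build_candidates=None)

    def _tree(self, genome, seed):
        depth, leaf, criterion = genome
        return DecisionTreeClassifier(
            max_depth=depth, min_samples_leaf=leaf, criterion=criterion,
            random_state=seed,
        )

    def evolve(self, score_fn, seed: int):
        """Run the GA; ``score_fn(estimator) -> mean CV kappa``."""
        rng = np.random.default_rng(seed)

        def random_genome():
            return (
                int(rng.choice(self.DEPTHS)),
                int(rng.choice(self.LEAVES)),
                str(rng.choice(self.CRITERIA)),
            )

        def mutate(genome):
            depth, leaf, criterion = genome
            which = rng.integers(3)
            if which == 0:
                depth = int(rng.choice(self.DEPTHS))
            elif which == 1:
                leaf = int(rng.choice(self.LEAVES))
            else:
                criterion = str(rng.choice(self.CRITERIA))
            return (depth, leaf, criterion)

        population = [random_genome() for _ in range(self.POP)]
        cache: dict[tuple, float] = {}

        def fitness(genome):
            if genome not in cache:
                cache[genome] = score_fn(self._tree(genome, seed))
            return cache[genome]

        for _ in range(self.GENERATIONS):
            scored = sorted(population, key=fitness, reverse=True)
            elite = scored[: self.POP // 2]
            children = []
            while len(elite) + len(children) < self.POP:
                a, b = (elite[int(rng.integers(len(elite)))] for _ in range(2))
                child = (a[0], b[1], a[2] if rng.random() < 0.5 else b[2])
                if rng.random() < 0.5:
                    child = mutate(child)
                children.append(child)
            population = elite + children

        best = max(population, key=fitness)
        return self._tree(best, seed)


#: registry-definition order; lexicographic order is used only for tie-breaks
DEFAULT_ALGORITHMS = [
    AlgorithmSpec("glm", _glm_candidates),
    AlgorithmSpec("svm", _svm_candidates),
    AlgorithmSpec("nnet", _nnet_candidates),
    AlgorithmSpec("mlp", _mlp_candidates),
    AlgorithmSpec("random_forest", _rf_candidates),
    AlgorithmSpec("knn", _knn_candidates),
    AlgorithmSpec("ada", _ada_candidates),
    GeneticTreeSpec(),
    AlgorithmSpec("rpart", _rpart_candidates),
]


class ModelRegistry:
    """Named constructors for the supported algorithm families."""

    def __init__(self, specs=None):
        specs = list(specs) if specs is not None else list(DEFAULT_ALGORITHMS)
        self._specs = {s.name: s for s in specs}
        if len(self._specs) != len(specs):
            raise ValueError("duplicate algorithm names in registry")

    def names(self) -> list[str]:
        return list(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __getitem__(self, name: str) -> AlgorithmSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"unknown algorithm {name!r}; available: {', '.join(self._specs)}"
            ) from None

    def subset(self, names) -> "ModelRegistry":
        return ModelRegistry([self[n] for n in names])


def default_registry() -> ModelRegistry:
    return ModelRegistry()


# ---------------------------------------------------------------------------
# trained models


@dataclass
class TrainedModel:
    """A fitted classifier plus its CV metadata and feature names."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    folds: int
    seed: int
    optimized_metric: str
    class_counts: dict[str, int]
    cv_metrics: PerformanceMetrics | None = None

    def _feature_matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ValueError(
                f"enrichment table lacks feature column(s): {', '.join(missing)}"
            )
        return table[self.feature_names].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted MAE/BAE status for each table row (index order)."""
        return self.estimator.predict(self._feature_matrix(table))

    def predict_score(self, table: pd.DataFrame) -> np.ndarray | None:
        """P(MAE) per row when the algorithm family yields probabilities."""
        est = self.estimator
        if not hasattr(est, "predict_proba"):
            return None
        proba = est.predict_proba(self._feature_matrix(table))
        classes = list(est.classes_)
        if MAE not in classes:
            return None
        return proba[:, classes.index(MAE)]


def _mean_or_none(values) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def _cv_mean_metrics(estimator, X, y, splits, seed) -> PerformanceMetrics:
    """Mean per-fold metrics for one candidate over fixed CV splits."""
    per_fold = []
    for train_idx, test_idx in splits:
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        truth_f = dict(zip(map(str, test_idx), y[test_idx]))
        pred_f = dict(zip(map(str, test_idx), pred))
        from .evaluation import confusion

        per_fold.append(metrics(confusion(truth_f, pred_f)))
    return PerformanceMetrics(
        precision=_mean_or_none([m.precision for m in per_fold]),
        recall=_mean_or_none([m.recall for m in per_fold]),
        f1=_mean_or_none([m.f1 for m in per_fold]),
        kappa=float(np.mean([m.kappa for m in per_fold])),
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        support_mae=int(np.sum(y == MAE)),
        support_bae=int(np.sum(y == BAE)),
    )


def _resubstitution_metrics(estimator, X, y) -> PerformanceMetrics:
    pred = estimator.predict(X)
    from .evaluation import confusion

    truth = dict(zip(map(str, range(len(y))), y))
    predicted = dict(zip(map(str, range(len(y))), pred))
    return metrics(confusion(truth, predicted))


def train_all(
    X: pd.DataFrame,
    y: np.ndarray,
    registry: ModelRegistry | None = None,
    folds: int = 5,
    seed: int = 0,
    full_fit: bool = False,
) -> tuple[list[TrainedModel], pd.DataFrame]:
    """Train every registry entry; return the models and a summary table.

    For each algorithm, candidates are scored by mean kappa over stratified
    k-fold CV (one shared fold assignment per algorithm, derived from the
    master seed plus the registry index); the best candidate is refit on
    all training data. With ``full_fit`` the CV step is skipped and the
    first candidate of each family is fit on the complete training set,
    with resubstitution metrics reported and ``folds`` recorded as 0.
    """
    registry = registry or default_registry()
    feature_names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    class_counts = {
        MAE: int(np.sum(y == MAE)), BAE: int(np.sum(y == BAE)),
    }
    if not full_fit:
        if folds < 2:
            raise ValueError("cross-validation requires folds >= 2")
        min_class = min(class_counts.values())
        if min_class < folds:
            raise ValueError(
                f"smallest class has {min_class} genes, fewer than "
                f"{folds} folds; reduce --folds or use full-fit training"
            )

    models: list[TrainedModel] = []
    rows = []
    for index, name in enumerate(registry.names()):
        spec = registry[name]
        algo_seed = seed + index
        if full_fit:
            estimator = _first_candidate(spec, len(feature_names), algo_seed)
            estimator.fit(Xa, y)
            cv = _resubstitution_metrics(estimator, Xa, y)
            used_folds = 0
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=algo_seed)
            splits = list(skf.split(Xa, y))

            def score(est):
                return _cv_mean_metrics(est, Xa, y, splits, algo_seed).kappa

            if isinstance(spec, GeneticTreeSpec):
                best = spec.evolve(score, algo_seed)
            else:
                candidates = spec.candidates(len(feature_names), algo_seed)
                scores = [score(c) for c in candidates]
                best = candidates[int(np.argmax(scores))]
            cv = _cv_mean_metrics(best, Xa, y, splits, algo_seed)
            estimator = clone(best)
            estimator.fit(Xa, y)
            used_folds = folds

        model = TrainedModel(
            algorithm=name,
            estimator=estimator,
            feature_names=feature_names,
            folds=used_folds,
            seed=algo_seed,
            optimized_metric="kappa",
            class_counts=class_counts,
            cv_metrics=cv,
        )
        models.append(model)
        rows.append({
            "algorithm": name,
            "precision": cv.precision,
            "recall": cv.recall,
            "F1": cv.f1,
            "kappa": cv.kappa,
            "accuracy": cv.accuracy,
            "folds": used_folds,
            "seed": algo_seed,
        })
        logger.info("trained %-14s kappa=%.3f F1=%s", name, cv.kappa,
                    f"{cv.f1:.3f}" if cv.f1 is not None else "undefined")

    summary = pd.DataFrame(rows)
    return models, summary


def _first_candidate(spec: AlgorithmSpec, n_features: int, seed: int):
    if isinstance(spec, GeneticTreeSpec):
        return DecisionTreeClassifier(max_depth=4, random_state=seed)
    return clone(spec.candidates(n_features, seed)[0])


_METRIC_FIELD = {"f1": "f1", "precision": "precision", "recall": "recall",
                 "kappa": "kappa"}


def select_best(models: list[TrainedModel], metric: str = "f1") -> TrainedModel:
    """Model maximizing the chosen CV metric; ties break lexicographically.

    F1 is the default because it balances precision (few false MAE calls)
    against recall (coverage of the true MAE set).
    """
    if not models:
        raise ValueError("no models to select from")
    if metric not in _METRIC_FIELD:
        raise ValueError(f"unknown selection metric {metric!r}")
    fieldname = _METRIC_FIELD[metric]
    values = []
    for m in models:
        v = m.cv_metrics.get(fieldname) if m.cv_metrics else None
        if v is None:
            raise ValueError(
                f"model {m.algorithm}: metric {metric} is undefined; "
                "choose another selection metric"
            )
        values.append(v)
    best_value = max(values)
    tied = sorted(
        m.algorithm for m, v in zip(models, values) if v == best_value
    )
    if len(tied) > 1:
        logger.info("tie on %s=%.4f between %s; choosing %s",
                    metric, best_value, ", ".join(tied), tied[0])
    winner = tied[0]
    return next(m for m in models if m.algorithm == winner)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model with a format-version guard (joblib)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a serialized model; reject foreign versions and corrupt files."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a chromae model file")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
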