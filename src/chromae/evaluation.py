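"""Confusion matrices and performance metrics, with MAE as the positive class.

Precision is the fraction of correct MAE predictions among all genes
predicted MAE; recall is the fraction of true MAE genes recovered; F1 is
their harmonic mean; Cohen's kappa is chance-corrected agreement,
(p_o - p_e)/(1 - p_e). Zero-denominator ratios are reported as undefined
(None), never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MAE",
    "BAE",
    "ConfusionMatrix",
    "PerformanceMetrics",
    "confusion",
    "metrics",
    "evaluate_on_testset",
    "write_metrics",
]

MAE = "MAE"
BAE = "BAE"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with MAE positive: tp/fn over true MAE, fp/tn over true BAE."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one gene")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Derived metrics; None marks an undefined (0/0) ratio."""

    precision: float | None
    recall: float | None
    f1: float | None
    kappa: float
    accuracy: float
    support_mae: int
    support_bae: int

    def get(self, name: str) -> float | None:
        return getattr(self, name)


def confusion(
    truth: dict[str, str], predictions: dict[str, str]
) -> ConfusionMatrix:
    """Confusion matrix over genes present in both truth and predictions.

    Genes missing from either side (e.g. filtered at prediction time) are
    excluded from the counts.
    """
    common = truth.keys() & predictions.keys()
    if not common:
        raise ValueError("no genes shared between truth labels and predictions")
    tp = fp = fn = tn = 0
    for g in common:
        t, p = truth[g], predictions[g]
        if t not in (MAE, BAE):
            raise ValueError(f"gene {g}: unknown truth status {t!r}")
        if p not in (MAE, BAE):
            raise ValueError(f"gene {g}: unknown predicted status {p!r}")
        if t == MAE:
            tp += p == MAE
            fn += p == BAE
        else:
            fp += p == MAE
            tn += p == BAE
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, denom: int) -> float | None:
    return num / denom if denom else None


def metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """Precision, recall, F1, Cohen's kappa and accuracy from a matrix."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)

    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn)
        + (cm.fn + cm.tn) * (cm.fp + cm.tn)
    ) / (n * n)
    kappa = 0.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)

    return PerformanceMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        kappa=kappa,
        accuracy=p_o,
        support_mae=cm.tp + cm.fn,
        support_bae=cm.fp + cm.tn,
    )


def evaluate_on_testset(
    model,
    table: pd.DataFrame,
    truth: dict[str, str],
    genes=None,
    expression: dict[str, float] | None = None,
    min_length: int = 0,
    min_expression: float = 0.0,
) -> tuple[PerformanceMetrics, ConfusionMatrix, float]:
    """Predict on a held-out table and score against truth labels.

    Composition predict -> confusion -> metrics. Returns the metrics, the
    matrix, and the truth MAE prevalence over the evaluated genes (MAE
    genes are typically a 5-20% minority, so report the imbalance).
    """
    from .prediction import apply_filters, predict_status

    if genes is not None:
        callable_ids, filtered = apply_filters(
            genes, expression, min_length, min_expression
        )
    else:
        callable_ids, filtered = set(table.index), []
    preds = predict_status(model, table, callable_ids)
    called = {row.gene_id: row.status for row in preds if row.status is not None}
    cm = confusion(truth, called)
    prevalence = (cm.tp + cm.fn) / cm.total
    return metrics(cm), cm, prevalence


def write_metrics(
    pm: PerformanceMetrics, cm: ConfusionMatrix, path: str | Path
) -> None:
    """Write metrics and the confusion matrix as a two-section TSV."""
    path = Path(path)
    fmt = lambda v: "" if v is None else f"{v:.6f}"  # noqa: E731
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name in ("precision", "recall", "f1", "kappa", "accuracy"):
            fh.write(f"{name}\t{fmt(pm.get(name))}\n")
        fh.write(f"support_MAE\t{pm.support_mae}\n")
        fh.write(f"support_BAE\t{pm.support_bae}\n")
        fh.write("\ncount\tvalue\n")
        for name in ("tp", "fp", "fn", "tn"):
            fh.write(f"{name}\t{getattr(cm, name)}\n")
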