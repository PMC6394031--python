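"""Genome-wide MAE/BAE prediction with gene-length and expression filters.

Each gene in the enrichment table receives either the classifier's call
(with a probability score when the algorithm family exposes one) or a
filter reason: too short, too lowly expressed, or missing from the
annotation. The score threshold is the model's native 0.5; no threshold
tuning is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import GeneInterval
from .training import TrainedModel

__all__ = [
    "PredictionRow",
    "apply_filters",
    "predict_status",
    "write_predictions",
    "read_predictions",
]

#: filter reasons, in the precedence order they are checked
SHORT_GENE = "short_gene"
LOW_EXPRESSION = "low_expression"
MISSING_FEATURE = "missing_feature"


@dataclass(frozen=True)
class PredictionRow:
    gene_id: str
    status: str | None  # MAE/BAE, or None when filtered
    score: float | None  # P(MAE) when available
    filtered_reason: str | None


def apply_filters(
    genes: list[GeneInterval],
    expression: dict[str, float] | None = None,
    min_length: int = 1000,
    min_expression: float = 0.0,
) -> tuple[set[str], list[tuple[str, str]]]:
    """Partition genes into callable IDs and (gene_id, reason) filtered pairs.

    A gene is callable iff its length >= min_length and, when an expression
    map is supplied, its expression >= min_expression; genes absent from a
    supplied expression map are filtered as low_expression. The expression
    filter compares in whatever units the user's file uses.
    """
    if min_length < 0 or min_expression < 0:
        raise ValueError("filter thresholds must be >= 0")
    callable_ids: set[str] = set()
    filtered: list[tuple[str, str]] = []
    for g in genes:
        if g.length < min_length:
            filtered.append((g.gene_id, SHORT_GENE))
        elif expression is not None and (
            g.gene_id not in expression
            or expression[g.gene_id] < min_expression
        ):
            filtered.append((g.gene_id, LOW_EXPRESSION))
        else:
            callable_ids.add(g.gene_id)
    return callable_ids, filtered


def predict_status(
    model: TrainedModel,
    table: pd.DataFrame,
    callable_ids: set[str] | None = None,
) -> list[PredictionRow]:
    """Predict MAE/BAE for every table row.

    Callable genes get the model's class decision (and score when
    available); the rest carry a filter reason. Genes in the table but
    outside the callable set that carry no explicit reason are marked
    missing_feature. Output order follows the table's row order, so the
    call set is invariant to row permutations.
    """
    if callable_ids is None:
        callable_ids = set(table.index)
    mask = table.index.isin(callable_ids)
    sub = table.loc[mask]
    rows: dict[str, PredictionRow] = {}
    if len(sub):
        statuses = model.predict(sub)
        scores = model.predict_score(sub)
        for i, gene_id in enumerate(sub.index):
            rows[gene_id] = PredictionRow(
                gene_id=str(gene_id),
                status=str(statuses[i]),
                score=float(scores[i]) if scores is not None else None,
                filtered_reason=None,
            )
    return [
        rows.get(
            g,
            PredictionRow(gene_id=str(g), status=None, score=None,
                          filtered_reason=MISSING_FEATURE),
        )
        for g in table.index
    ]


def attach_filter_reasons(
    predictions: list[PredictionRow], filtered: list[tuple[str, str]]
) -> list[PredictionRow]:
    """Replace placeholder reasons with the actual filter reasons."""
    reason_map = dict(filtered)
    out = []
    for row in predictions:
        if row.status is None and row.gene_id in reason_map:
            row = PredictionRow(row.gene_id, None, None,
                                reason_map[row.gene_id])
        out.append(row)
    return out


def read_expression(path: str | Path) -> dict[str, float]:
    """Read an expression TSV with header ``gene_id<TAB>value``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expression file needs gene_id and value columns")
    return {str(g): float(v) for g, v in zip(df["gene_id"], df["value"])}


def write_predictions(
    predictions: list[PredictionRow],
    path: str | Path,
    header_info: dict[str, object] | None = None,
) -> None:
    """Write predictions TSV with a commented header of run parameters."""
    with open(path, "w") as fh:
        for key, value in (header_info or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("gene_id\tstatus\tscore\tfiltered_reason\n")
        for row in predictions:
            score = "" if row.score is None else f"{row.score:.6f}"
            fh.write(
                f"{row.gene_id}\t{row.status or ''}\t{score}\t"
                f"{row.filtered_reason or ''}\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRow]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_id": str}, keep_default_na=False)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(PredictionRow(
            gene_id=rec.gene_id,
            status=rec.status or None,
            score=float(rec.score) if rec.score != "" else None,
            filtered_reason=rec.filtered_reason or None,
        ))
    return rows
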