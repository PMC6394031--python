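"""Per-gene enrichment: interval means, control floor, normalization, ranks.

The end product is the enrichment table: per gene and per mark, the
quantile rank in (0, 1] of the control-normalized mean signal. Ranks are
computed within-sample over the genes surviving all filters, making the
feature space scale-free across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import GeneInterval, derive_interval
from .coverage import CoverageTrack

__all__ = [
    "IntervalSignal",
    "ProcessParams",
    "mean_signal",
    "control_floor_filter",
    "normalize",
    "quantile_rank",
    "build_enrichment_table",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSignal:
    """Mean coverage of one mark over one gene interval (units per base)."""

    gene_id: str
    mark: str
    mean_signal: float


@dataclass
class ProcessParams:
    """Tunables of the enrichment stage.

    control_threshold is in track units (mean signal per base); genes whose
    control mean falls below it are dropped before normalization, which also
    guards the control-ratio against division by zero at the default
    pseudocount of 0.
    """

    interval_mode: str = "gene_body"  # or "promoter"
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    normalization: str = "control"  # or "length"
    control_threshold: float = 0.1
    pseudocount: float = 0.0


def mean_signal(track: CoverageTrack, interval: GeneInterval) -> IntervalSignal:
    """Mean per-base signal of *track* over the gene interval.

    Uncovered bases count as 0 (see coverage module); errors for absent
    chromosomes or zero-length intervals propagate from the track.
    """
    value = track.mean(interval.chrom, interval.start, interval.end)
    return IntervalSignal(gene_id=interval.gene_id, mark="", mean_signal=value)


def control_floor_filter(
    control_signals: dict[str, float], threshold: float
) -> tuple[set[str], set[str]]:
    """Split gene IDs into (kept, removed) by the control-signal floor.

    A gene is kept iff its control mean signal >= threshold.
    """
    if threshold < 0:
        raise ValueError("control threshold must be >= 0")
    kept = {g for g, v in control_signals.items() if v >= threshold}
    removed = set(control_signals) - kept
    if control_signals and not kept:
        logger.warning(
            "control floor %.4g removed every gene (%d)", threshold,
            len(removed),
        )
    return kept, removed


def normalize(
    chip: float,
    control: float | None,
    interval_length: int,
    mode: str = "control",
    pseudocount: float = 0.0,
) -> float:
    """Normalize a ChIP mean signal.

    mode="control": (chip + pseudocount) / (control + pseudocount).
    mode="length": the per-base mean itself — the mean over the interval is
    already total signal divided by feature length.
    """
    if mode == "length":
        return chip
    if mode != "control":
        raise ValueError(f"unknown normalization mode: {mode!r}")
    if control is None:
        raise ValueError("control normalization requires a control signal")
    denom = control + pseudocount
    if denom == 0:
        raise ZeroDivisionError(
            "control + pseudocount is 0; raise the control threshold or "
            "set a positive pseudocount"
        )
    return (chip + pseudocount) / denom


def quantile_rank(values: np.ndarray | list[float]) -> np.ndarray:
    """Fractional quantile rank in (0, 1].

    Average competition rank (ties get the mean of the ranks they span)
    divided by n, so the maximum maps to 1 and n untied values produce
    exactly {1/n, ..., 1}.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile_rank of an empty vector is undefined")
    if np.isnan(arr).any():
        raise ValueError("quantile_rank input contains NaN")
    return rankdata(arr, method="average") / arr.size


def build_enrichment_table(
    tracks: dict[str, CoverageTrack],
    control: CoverageTrack | None,
    genes: list[GeneInterval],
    params: ProcessParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full enrichment stage: intervals → means → floor filter → normalize → rank.

    Returns ``(table, report)``: *table* is indexed by gene_id with one
    quantile-rank column per mark; *report* lists removed genes with their
    reason (``below_control_floor``). Ranks are computed after all
    filtering, so only surviving genes define the rank distribution.
    """
    if not tracks:
        raise ValueError("at least one mark track is required")
    params = params or ProcessParams()
    if params.normalization == "control" and control is None:
        raise ValueError("normalization='control' requires a control track")

    intervals = [
        derive_interval(
            g, params.interval_mode,
            params.promoter_upstream, params.promoter_downstream,
        )
        for g in genes
    ]

    # control floor
    if control is not None:
        control_means = {
            iv.gene_id: control.mean(iv.chrom, iv.start, iv.end)
            for iv in intervals
        }
        kept_ids, removed_ids = control_floor_filter(
            control_means, params.control_threshold
        )
    else:
        control_means = {}
        kept_ids = {iv.gene_id for iv in intervals}
        removed_ids = set()

    surviving = [iv for iv in intervals if iv.gene_id in kept_ids]
    report = pd.DataFrame(
        {
            "gene_id": [iv.gene_id for iv in intervals
                        if iv.gene_id in removed_ids],
            "reason": "below_control_floor",
        },
        columns=["gene_id", "reason"],
    )

    columns: dict[str, np.ndarray] = {}
    for mark, track in tracks.items():
        raw = np.array(
            [
                normalize(
                    track.mean(iv.chrom, iv.start, iv.end),
                    control_means.get(iv.gene_id),
                    iv.length,
                    mode=params.normalization,
                    pseudocount=params.pseudocount,
                )
                for iv in surviving
            ]
        )
        columns[mark] = quantile_rank(raw) if len(raw) else raw

    table = pd.DataFrame(
        columns, index=pd.Index([iv.gene_id for iv in surviving],
                                name="gene_id")
    )
    return table, report


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an enrichment table as TSV (gene_id + one column per mark)."""
    table.to_csv(path, sep="\t", float_format="%.6f")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read an enrichment table written by :func:`write_table`."""
    table = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
    if table.empty and table.columns.empty:
        raise ValueError(f"enrichment table {path} has no mark columns")
    return table
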