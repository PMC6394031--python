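"""Gene annotation I/O, interval derivation, and default gene exclusions.

All internal coordinates are 0-based half-open; conversion from GTF's
1-based inclusive convention happens at the parse boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "GeneInterval",
    "ExclusionSets",
    "AnnotationError",
    "read_annotation",
    "read_gene_list",
    "derive_interval",
    "apply_exclusions",
    "default_exclusion_sets",
]

#: chromosome names treated as the X chromosome
X_CHROM_NAMES = frozenset({"chrX", "X"})


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GeneInterval:
    """One annotated gene: 0-based half-open genomic interval plus strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval "
                f"[{self.start}, {self.end}) — need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be one of + - . "
                f"(got {self.strand!r})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site; undefined for strand '.'."""
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end
        raise AnnotationError(
            f"gene {self.gene_id}: TSS undefined for strand '.'"
        )


@dataclass
class ExclusionSets:
    """Gene IDs excluded from analysis by default.

    X-linkage is resolved both by explicit ID membership and by chromosome
    name ({chrX, X}); imprinted/olfactory membership is exact string match
    on ``gene_id`` (and ``gene_name`` when present).
    """

    x_linked: set[str] = field(default_factory=set)
    imprinted: set[str] = field(default_factory=set)
    olfactory: set[str] = field(default_factory=set)

    def reason_for(self, gene: GeneInterval) -> str | None:
        """Return the exclusion reason for *gene*, or None if it survives."""
        names = {gene.gene_id}
        if gene.gene_name:
            names.add(gene.gene_name)
        if gene.chrom in X_CHROM_NAMES or names & self.x_linked:
            return "x_linked"
        if names & self.imprinted:
            return "imprinted"
        if names & self.olfactory:
            return "olfactory"
        return None


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one ID per line, '#' comments allowed."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids


def default_exclusion_sets() -> ExclusionSets:
    """Exclusion sets from the packaged human imprinted/olfactory lists.

    The shipped lists are editable defaults (human gene symbols); X-linkage
    is handled by chromosome name so the x_linked ID set starts empty.
    """
    data = resources.files("chromae") / "data"
    return ExclusionSets(
        x_linked=set(),
        imprinted=_read_resource(data / "imprinted_human.txt"),
        olfactory=_read_resource(data / "olfactory_human.txt"),
    )


def _read_resource(res) -> set[str]:
    ids = set()
    for line in res.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


# ---------------------------------------------------------------------------
# annotation parsing

_GTF_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')
_GTF_GENE_NAME_RE = re.compile(r'gene_name\s+"([^"]+)"')


def read_annotation(path: str | Path, format: str = "bed") -> list[GeneInterval]:
    """Read gene records from a BED6 or GTF file.

    BED intervals are taken verbatim (already 0-based half-open); GTF
    ``gene`` feature lines are converted from 1-based inclusive. For GTF,
    transcript/exon records are ignored.

    Raises
    ------
    AnnotationError
        On a malformed line (naming its line number) or a duplicated
        gene_id.
    """
    if format == "bed":
        genes = list(_parse_bed(path))
    elif format == "gtf":
        genes = list(_parse_gtf(path))
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _parse_bed(path: str | Path) -> Iterable[GeneInterval]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(
                    f"{path}:{lineno}: BED line needs >= 4 fields "
                    f"(got {len(fields)})"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                yield GeneInterval(
                    gene_id=fields[3], chrom=fields[0],
                    start=start, end=end, strand=strand,
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc


def _parse_gtf(path: str | Path) -> Iterable[GeneInterval]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: GTF line needs 9 fields "
                    f"(got {len(fields)})"
                )
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            m = _GTF_GENE_ID_RE.search(fields[8])
            if m is None:
                raise AnnotationError(
                    f"{path}:{lineno}: gene record lacks gene_id attribute"
                )
            name_m = _GTF_GENE_NAME_RE.search(fields[8])
            try:
                yield GeneInterval(
                    gene_id=m.group(1), chrom=fields[0],
                    start=start1 - 1, end=end1, strand=fields[6],
                    gene_name=name_m.group(1) if name_m else None,
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# interval derivation and exclusions


def derive_interval(
    gene: GeneInterval,
    mode: str = "gene_body",
    promoter_upstream: int = 2000,
    promoter_downstream: int = 2000,
) -> GeneInterval:
    """Interval to summarize: the gene body, or a TSS-centred promoter window.

    The promoter window is [TSS - upstream, TSS + downstream) on the +
    strand and its strand mirror on -, clipped at coordinate 0. Extents
    default to 2 kb each side, a common ChIP-seq convention.
    """
    if mode == "gene_body":
        return gene
    if mode != "promoter":
        raise ValueError(f"unknown interval mode: {mode!r}")
    if promoter_upstream < 0 or promoter_downstream < 0:
        raise ValueError("promoter extents must be >= 0")
    tss = gene.tss  # raises for strand "."
    if gene.strand == "+":
        start, end = tss - promoter_upstream, tss + promoter_downstream
    else:
        start, end = tss - promoter_downstream, tss + promoter_upstream
    return replace(gene, start=max(start, 0), end=end)


def apply_exclusions(
    genes: list[GeneInterval],
    exclusions: ExclusionSets,
    enabled: bool = True,
) -> tuple[list[GeneInterval], list[tuple[str, str]]]:
    """Drop excluded genes (X-linked / imprinted / olfactory).

    Returns the surviving genes in input order and a list of
    ``(gene_id, reason)`` pairs for the removed ones. Unknown IDs in the
    exclusion lists are ignored.
    """
    if not enabled:
        return list(genes), []
    kept: list[GeneInterval] = []
    removed: list[tuple[str, str]] = []
    for g in genes:
        reason = exclusions.reason_for(g)
        if reason is None:
            kept.append(g)
        else:
            removed.append((g.gene_id, reason))
    return kept, removed
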