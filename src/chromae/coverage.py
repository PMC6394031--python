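"""Coverage-track access: bigWig via pyBigWig, bedGraph as a text fallback.

Interval means treat uncovered bases as signal 0, so the mean is
sum(signal over covered bases) / interval length. This makes the result
independent of the track's internal block structure and equates absence
of reads with zero coverage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["CoverageTrack", "BigWigTrack", "BedGraphTrack", "open_track", "TrackError"]


class TrackError(ValueError):
    """Raised for malformed tracks or out-of-track queries."""


class CoverageTrack:
    """Per-base numeric signal queryable by (chrom, start, end)."""

    source: str

    def chroms(self) -> set[str]:
        raise NotImplementedError

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end); uncovered bases add 0."""
        raise NotImplementedError

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Arithmetic mean over [start, end) with uncovered bases as 0."""
        if end <= start:
            raise TrackError(
                f"zero-length interval {chrom}:{start}-{end} in {self.source}"
            )
        if chrom not in self.chroms():
            raise TrackError(
                f"chromosome {chrom!r} absent from track {self.source}"
            )
        return self.interval_sum(chrom, start, end) / (end - start)


class BigWigTrack(CoverageTrack):
    """bigWig-backed track (pyBigWig)."""

    def __init__(self, path: str | Path):
        import pyBigWig

        self.source = str(path)
        self._bw = pyBigWig.open(self.source)
        if self._bw is None or not self._bw.isBigWig():
            raise TrackError(f"{path} is not a bigWig file")
        self._chroms = dict(self._bw.chroms())

    def chroms(self) -> set[str]:
        return set(self._chroms)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        # clip to the declared chrom length; bases beyond it are uncovered
        qend = min(end, self._chroms[chrom])
        if qend <= start:
            return 0.0
        total = self._bw.stats(chrom, start, qend, type="sum", exact=True)[0]
        return float(total) if total is not None else 0.0

    def close(self) -> None:
        self._bw.close()


class BedGraphTrack(CoverageTrack):
    """bedGraph-backed track (4-column text; track lines ignored).

    Intervals are 0-based half-open. Overlapping lines are rejected as an
    error rather than resolved, since their meaning is ambiguous.
    """

    def __init__(self, path: str | Path):
        self.source = str(path)
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise TrackError(
                        f"{path}:{lineno}: bedGraph line needs 4 fields"
                    )
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError as exc:
                    raise TrackError(f"{path}:{lineno}: bad numeric field") from exc
                if end <= start:
                    raise TrackError(
                        f"{path}:{lineno}: empty interval {start}-{end}"
                    )
                per_chrom.setdefault(fields[0], []).append((start, end, value))

        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise TrackError(
                    f"{path}: overlapping bedGraph intervals on {chrom} "
                    f"around {starts[i + 1]}"
                )
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in rows], dtype=float)

    def chroms(self) -> set[str]:
        return set(self._starts)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        starts, ends = self._starts[chrom], self._ends[chrom]
        values = self._values[chrom]
        # entries overlapping [start, end): end_i > start and start_i < end
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        overlap = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(overlap * values[lo:hi]))


def open_track(path: str | Path, format: str | None = None) -> CoverageTrack:
    """Open a coverage track, inferring the format from the suffix if needed."""
    path = Path(path)
    if not path.exists():
        raise TrackError(f"track file not found: {path}")
    if format is None:
        if path.suffix.lower() in (".bw", ".bigwig"):
            format = "bigwig"
        elif path.suffix.lower() in (".bedgraph", ".bg", ".bdg"):
            format = "bedgraph"
        else:
            raise TrackError(
                f"cannot infer track format from suffix of {path}; "
                "pass format explicitly"
            )
    if format == "bigwig":
        return BigWigTrack(path)
    if format == "bedgraph":
        return BedGraphTrack(path)
    raise ValueError(f"unknown track format: {format!r}")
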