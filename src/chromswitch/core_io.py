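"""Genomic interval model and text-format readers/writers.

Coordinates are 0-based half-open (BED convention) throughout.  The module
provides the small set of domain types every analysis stage consumes --
scored peaks with summits, piecewise-constant signal tracks, paired-end
fragments and stranded gene models -- plus the interval arithmetic
(merging, overlap queries) the stages share.

Only plain-text formats are handled: narrowPeak / BED for intervals,
bedGraph for signal, TSV for genes and tabular outputs.  Binary bigwig/BAM
parsing is deliberately out of scope.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class ValidationError(ValueError):
    """Input violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base; book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """Scored interval with a summit (the base of maximal enrichment).

    ``score`` is on the -log10 p-value scale of MACS2 narrowPeak column 8.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end})"
            )
        if self.score < 0:
            raise ValidationError("peak score must be >= 0")


@dataclass(frozen=True)
class Fragment:
    """A sequenced paired-end fragment."""

    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene; the TSS is the 5' end of the gene interval."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class SignalTrack:
    """Piecewise-constant nonnegative genome signal, queryable by interval mean.

    Runs are stored per chromosome as sorted, disjoint (start, end, value)
    arrays.  Uncovered bases read as 0, so interval means are length-weighted
    with implicit zeros -- the same semantics as averaging a coverage track.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = runs

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not (0 <= start < end):
                raise ValidationError(f"bad run [{start}, {end}) on {chrom}")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"run value must be finite and >= 0: {value}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValidationError(
                    f"overlapping runs on {chrom}: [{starts[i]},{ends[i]}) and "
                    f"[{starts[i + 1]},{ends[i + 1]})"
                )
            runs[chrom] = (starts, ends, values)
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def chrom_span(self, chrom: str) -> int:
        """Rightmost covered coordinate on the chromosome (0 if uncovered)."""
        if chrom not in self._runs:
            return 0
        return int(self._runs[chrom][1][-1])

    def total(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end)."""
        if chrom not in self._runs or end <= start:
            return 0.0
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValidationError("query interval must be non-empty")
        return self.total(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, bin_size: int, n_bins: int) -> np.ndarray:
        """Means over the fixed grid [0, bin), [bin, 2*bin), ... on one chromosome."""
        edges = np.arange(n_bins + 1, dtype=np.int64) * bin_size
        out = np.zeros(n_bins, dtype=float)
        for b in range(n_bins):
            out[b] = self.total(chrom, int(edges[b]), int(edges[b + 1]))
        return out / bin_size

    def iter_runs(self):
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


class IntervalIndex:
    """Sorted per-chromosome interval lookup for >=1 bp overlap queries.

    Handles possibly-overlapping stored intervals by tracking the running
    maximum of interval ends, so queries stay O(log n) after O(n log n) build.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = [s for s, _ in items]
            max_ends: list[int] = []
            running = 0
            for _, e in items:
                running = max(running, e)
                max_ends.append(running)
            self._index[chrom] = (starts, max_ends)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._index:
            return False
        starts, max_ends = self._index[chrom]
        i = bisect_right(starts, end - 1)  # intervals starting before `end`
        return i > 0 and max_ends[i - 1] > start

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return self.overlaps(iv.chrom, iv.start, iv.end)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals overlapping by >=1 bp; book-ended intervals stay separate.

    Output is sorted and disjoint and covers exactly the union of input bases.
    Strand is dropped (merged regions are unstranded).
    """
    items = sorted((iv.chrom, iv.start, iv.end) for iv in intervals)
    out: list[GenomicInterval] = []
    for chrom, start, end in items:
        if out and out[-1].chrom == chrom and start < out[-1].end:
            if end > out[-1].end:
                out[-1] = GenomicInterval(chrom, out[-1].start, end)
        else:
            out.append(GenomicInterval(chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# readers


def _split_line(line: str, path: str, lineno: int, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise ParseError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def read_peaks(path: str | Path, p_threshold: float | None = 1e-5) -> list[Peak]:
    """Read narrowPeak (BED6+4) or BED6/BED3 peaks, filtered by significance.

    narrowPeak column 8 holds -log10(p); peaks with column 8 below
    -log10(p_threshold) are dropped.  The summit is start + column-10 offset,
    or the interval midpoint when the offset is -1 or the file is plain BED
    (which carries no p-value, so no filter applies).  Output is sorted by
    (chrom, start).
    """
    min_logp = -math.inf if p_threshold is None else -math.log10(p_threshold)
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, str(path), lineno, 3)
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            name = fields[3] if len(fields) > 3 else "."
            if len(fields) >= 10:  # narrowPeak
                try:
                    logp = float(fields[7])
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad narrowPeak fields: {exc}"
                    ) from None
                if logp < min_logp:
                    continue
                if offset >= end - start:
                    raise ValidationError(
                        f"{path}:{lineno}: summit offset {offset} >= length "
                        f"{end - start}"
                    )
                summit = start + offset if offset >= 0 else (start + end) // 2
                score = max(logp, 0.0)
            else:
                summit = (start + end) // 2
                score = float(fields[4]) if len(fields) > 4 else 0.0
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), summit, score, name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def read_signal(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (runs may be unsorted)."""
    records = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, str(path), lineno, 4)
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    try:
        return SignalTrack.from_records(records)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def read_fragments(path: str | Path) -> list[Fragment]:
    """Read a 3+-column BED of paired-end fragment intervals."""
    fragments = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, str(path), lineno, 3)
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            fragments.append(Fragment(iv))
    return fragments


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a gene TSV with columns gene_id, chrom, start, end, strand.

    A header line starting with 'gene_id' is tolerated.
    """
    genes = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line, str(path), lineno, 5)
            if lineno == 1 and fields[0] == "gene_id":
                continue
            try:
                iv = GenomicInterval(
                    fields[1], int(fields[2]), int(fields[3]), fields[4]
                )
                genes.append(GeneModel(fields[0], iv))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


# ---------------------------------------------------------------------------
# writers


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak; columns 7-9 carry score on the -log10 p scale."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            offset = p.summit - iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"0\t{p.score:g}\t{p.score:g}\t{offset}\n"
            )


def write_signal(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str]) -> None:
    """Write rows as plain TSV with a single header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
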