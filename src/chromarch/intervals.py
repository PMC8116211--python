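"""Genomic intervals, BED-dialect I/O and peak/annotation overlap statistics.

Coordinates are 0-based half-open internally.  Two file dialects are read:

* ``bed0`` — standard BED3/BED6, 0-based half-open.
* ``tsv1`` — tab-separated tables with 1-based inclusive coordinates
  (the convention of many supplementary spreadsheets); converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
from intervaltree import IntervalTree

from chromarch.genome import GenomeAssembly

Dialect = Literal["bed0", "tsv1"]


@dataclass(frozen=True)
class GenomicInterval:
    """A strandless interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with overlap algebra."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals], dtype=int)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def validate(self, assembly: GenomeAssembly) -> None:
        for iv in self.intervals:
            if iv.chrom not in assembly:
                raise ValueError(f"chromosome {iv.chrom!r} not in assembly {assembly.name!r}")
            if iv.end > assembly.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {assembly.length(iv.chrom)}"
                )

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        by_chrom: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return by_chrom


class BedParseError(ValueError):
    """Raised for malformed BED/TSV lines; carries the offending line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_bed(
    path: str | Path,
    dialect: Dialect = "bed0",
    assembly: GenomeAssembly | None = None,
    label: str = "",
) -> IntervalSet:
    """Read intervals from a BED3+/TSV file.

    ``tsv1`` input is converted from 1-based inclusive to 0-based half-open
    (start decremented by one).  A single header line starting with a
    non-numeric second column is skipped.  Empty files yield empty sets.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise BedParseError(path, lineno, f"non-integer coordinates {fields[1:3]}") from None
            if dialect == "tsv1":
                start -= 1
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            if start >= end or start < 0:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end})")
            intervals.append(GenomicInterval(chrom, start, end, score=score))
    out = IntervalSet(intervals, label=label or str(path))
    if assembly is not None:
        out.validate(assembly)
    return out


def write_bed(ivset: IntervalSet, path: str | Path, dialect: Dialect = "bed0") -> None:
    """Write intervals as BED3 (or 1-based TSV with a header for ``tsv1``)."""
    with open(path, "w") as fh:
        if dialect == "tsv1":
            fh.write("chrom\tstart\tend\n")
        for iv in ivset:
            start = iv.start + 1 if dialect == "tsv1" else iv.start
            if iv.score is not None:
                fh.write(f"{iv.chrom}\t{start}\t{iv.end}\t.\t{iv.score:g}\n")
            else:
                fh.write(f"{iv.chrom}\t{start}\t{iv.end}\n")


def sniff_dialect(path: str | Path) -> Dialect:
    """Guess the coordinate convention of a table.

    Files whose first line looks like a header (non-numeric second column)
    are treated as 1-based supplementary-style tables; plain headerless
    files as BED.
    """
    with open(path) as fh:
        first = fh.readline().split()
    if len(first) >= 3:
        try:
            int(first[1])
        except ValueError:
            return "tsv1"
    return "bed0"


def classify_by_annotation(
    peaks: IntervalSet,
    annotation: IntervalSet,
    min_overlap_bp: int = 1,
    mode: Literal["any-overlap", "midpoint"] = "any-overlap",
) -> tuple[IntervalSet, IntervalSet]:
    """Partition ``peaks`` into (inside, outside) an annotation.

    A peak is *inside* iff it overlaps the annotation by at least
    ``min_overlap_bp`` base pairs (``any-overlap`` mode), or iff its
    midpoint falls within an annotated interval (``midpoint`` mode).
    The two returned sets partition the input exactly.
    """
    trees = annotation.trees()
    inside, outside = [], []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        hit = False
        if tree is not None:
            if mode == "midpoint":
                hit = bool(tree.overlaps_point(peak.midpoint))
            else:
                overlaps = tree.overlap(peak.start, peak.end)
                total = sum(
                    min(o.end, peak.end) - max(o.begin, peak.start) for o in overlaps
                )
                hit = total >= min_overlap_bp
        (inside if hit else outside).append(peak)
    return (
        IntervalSet(inside, label=f"{peaks.label}:inside"),
        IntervalSet(outside, label=f"{peaks.label}:outside"),
    )


@dataclass(frozen=True)
class WidthStats:
    """Box-plot summary of interval widths.

    Median and quartiles use linear-interpolation quantiles; whiskers are
    the Tukey convention, Q1 - 1.5*IQR and Q3 + 1.5*IQR.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[int, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def width_stats(ivset: IntervalSet) -> WidthStats:
    """Box-plot statistics of interval widths; errors on an empty set."""
    if len(ivset) == 0:
        raise ValueError("width_stats requires a non-empty interval set")
    w = ivset.widths()
    q1, med, q3 = np.percentile(w, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(int(x) for x in w[(w < lo) | (w > hi)])
    return WidthStats(len(w), float(med), float(q1), float(q3), float(lo), float(hi), outliers)


def assign_to_compartments(peaks: IntervalSet, track) -> IntervalSet:
    """Label each peak A/B/unassigned by the compartment of its midpoint bin.

    ``track`` is a :class:`chromarch.compartments.CompartmentTrack`.  Peaks
    on chromosomes absent from the track, or whose midpoint bin has an
    undefined score, are labelled ``"unassigned"``.
    """
    labelled = []
    for peak in peaks:
        label = track.label_at(peak.chrom, peak.midpoint)
        labelled.append(
            GenomicInterval(peak.chrom, peak.start, peak.end, score=peak.score, label=label)
        )
    return IntervalSet(labelled, label=f"{peaks.label}:compartments")


def subset_by_label(ivset: IntervalSet, label: str) -> IntervalSet:
    return IntervalSet([iv for iv in ivset if iv.label == label], label=f"{ivset.label}:{label}")
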