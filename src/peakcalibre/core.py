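"""Core genomic domain types and interval algebra.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  "Overlap" throughout the package means sharing at least
one base pair; touching intervals (``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The 15 coreMarks chromatin-state labels (Roadmap Epigenomics segmentation).
CORE15_STATES: tuple[str, ...] = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called peak region with its signal statistics.

    ``summit_offset`` is the summit position relative to ``interval.start``
    (the narrowPeak convention); ``None`` means unknown, in which case the
    effective summit falls back to the interval midpoint.
    """

    interval: GenomicInterval
    name: str
    fold_enrichment: float
    neglog10_p: float
    neglog10_q: float
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValueError(f"fold_enrichment must be > 0 for {self.name}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak {self.name}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def effective_summit(self) -> int:
        """Absolute summit coordinate; midpoint if the summit is unknown."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, TSS and (optional) exon structure.

    The TSS is strand-dependent: ``span.start`` on "+", ``span.end - 1``
    on "-" (the last covered base, since coordinates are half-open).
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.chrom != self.span.chrom:
            raise ValueError(f"gene {self.gene_id}: chrom mismatch with span")
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


@dataclass(frozen=True)
class ChromatinStateSegment:
    """A labelled segment from a 15-state chromatin segmentation."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in CORE15_STATES:
            raise ValueError(f"unknown chromatin state {self.state!r}")


def overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class _ChromIndex:
    """Merged, sorted per-chromosome subject intervals for overlap queries.

    Merging makes membership a single bisect: an interval ``[s, e)``
    overlaps some subject iff the merged interval whose start is the
    rightmost one ``< e`` ends after ``s``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    def overlaps(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        i = bisect_left(starts, iv.end) - 1  # rightmost merged start < end
        return i >= 0 and self._ends[iv.chrom][i] > iv.start


def any_overlap_flags(
    queries: Sequence[GenomicInterval | Peak],
    subjects: Iterable[GenomicInterval | Peak],
) -> list[bool]:
    """For each query, whether it shares >= 1 bp with any subject.

    Accepts ``Peak`` objects transparently (their intervals are used).
    The result is independent of the ordering of either collection.
    """
    index = _ChromIndex(_as_interval(s) for s in subjects)
    return [index.overlaps(_as_interval(q)) for q in queries]


def _as_interval(x: GenomicInterval | Peak) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def chromosome_name_mismatches(
    a: Iterable[str], b: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Chromosome names present in one collection but not the other.

    Matching elsewhere is exact string equality (no "chr" normalisation);
    callers use this to emit a validation warning.
    """
    sa, sb = set(a), set(b)
    return sa - sb, sb - sa
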