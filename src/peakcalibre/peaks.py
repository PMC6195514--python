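"""Peak QC filtering, closest-TSS association and genomic annotation.

Distances are measured from the peak's *effective summit* (the reported
summit, or the interval midpoint when unknown) to gene TSSs, unstranded
absolute distance; sign is then assigned relative to the gene's strand
(negative = summit upstream of the TSS).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .core import GeneModel, GenomicInterval, Peak, any_overlap_flags


class AnnotationCategory(str, Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    PROXIMAL = "PROXIMAL"     # <= 2 kb upstream of the closest TSS
    DISTAL = "DISTAL"         # 2-10 kb upstream
    FIVE_D = "FIVE_D"         # 10-100 kb upstream
    OTHER = "OTHER"


#: Upstream category bounds in bp, applied in order (nested thresholds).
UPSTREAM_BINS: tuple[tuple[AnnotationCategory, int], ...] = (
    (AnnotationCategory.PROXIMAL, 2_000),
    (AnnotationCategory.DISTAL, 10_000),
    (AnnotationCategory.FIVE_D, 100_000),
)


@dataclass(frozen=True)
class PeakGeneAssociation:
    """A peak paired with its closest-TSS gene."""

    peak_name: str
    gene_id: str
    distance: int
    signed_distance: int

    def __post_init__(self) -> None:
        if abs(self.signed_distance) != self.distance:
            raise ValueError("signed_distance magnitude must equal distance")


@dataclass
class FilterResult:
    retained: list[Peak]
    rejections: dict[str, str]          # peak name -> reason
    reason_counts: dict[str, int]       # reason -> count


def filter_peaks(
    peaks: Sequence[Peak],
    blacklist: Sequence[GenomicInterval],
    fe_cap: float = 50.0,
    q_max: float = 0.1,
) -> FilterResult:
    """Drop peaks with fold enrichment above ``fe_cap`` (strictly greater;
    a peak at exactly the cap is kept), q-value above ``q_max``, or any
    (>= 1 bp) blacklist overlap.

    A peak failing several checks is logged once, under the first failing
    reason in the fixed order fe_cap, q_max, blacklist, so that retained +
    rejections partition the input.
    """
    min_nlq = -math.log10(q_max)
    bl_flags = any_overlap_flags(peaks, blacklist) if blacklist else [False] * len(peaks)
    retained: list[Peak] = []
    rejections: dict[str, str] = {}
    counts = {"fe_cap": 0, "q_max": 0, "blacklist": 0}
    for peak, in_bl in zip(peaks, bl_flags):
        if peak.fold_enrichment > fe_cap:
            reason = "fe_cap"
        elif peak.neglog10_q < min_nlq - 1e-12:
            reason = "q_max"
        elif in_bl:
            reason = "blacklist"
        else:
            retained.append(peak)
            continue
        rejections[peak.name] = reason
        counts[reason] += 1
    return FilterResult(retained, rejections, counts)


class _TssIndex:
    """Per-chromosome sorted TSS positions with deterministic tie-breaking."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("empty gene set")
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._pos: dict[str, list[int]] = {}
        self._ids: dict[str, list[str]] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            self._pos[chrom] = [p for p, _ in pairs]
            self._ids[chrom] = [gid for _, gid in pairs]

    def closest(self, chrom: str, point: int) -> tuple[str, int] | None:
        """(gene_id, tss) minimizing |tss - point|; ties (including multiple
        genes at the same TSS) resolve to the lexicographically smallest
        gene_id.  None if the chromosome carries no gene."""
        pos = self._pos.get(chrom)
        if pos is None:
            return None
        ids = self._ids[chrom]
        i = bisect_left(pos, point)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                d = abs(pos[j] - point)
                if best is None or d < best:
                    best = d
        assert best is not None
        # All genes whose TSS sits at point - best or point + best compete.
        candidates: list[tuple[str, int]] = []
        for tss in (point - best, point + best):
            lo = bisect_left(pos, tss)
            hi = bisect_right(pos, tss)
            candidates.extend((ids[k], pos[k]) for k in range(lo, hi))
        gene_id, tss = min(candidates)
        return gene_id, tss


def associate_closest_tss(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, PeakGeneAssociation], list[str]]:
    """Map each peak to the gene whose TSS is closest to its effective summit.

    Returns (associations keyed by peak name, names of unassigned peaks —
    those on chromosomes without any gene).  The signed distance is
    negative when the summit lies upstream of the TSS relative to the
    gene's strand.
    """
    index = _TssIndex(genes)
    strand_of = {g.gene_id: g.strand for g in genes}
    associations: dict[str, PeakGeneAssociation] = {}
    unassigned: list[str] = []
    for peak in peaks:
        summit = peak.effective_summit
        hit = index.closest(peak.chrom, summit)
        if hit is None:
            unassigned.append(peak.name)
            continue
        gene_id, tss = hit
        delta = summit - tss
        signed = delta if strand_of[gene_id] == "+" else -delta
        associations[peak.name] = PeakGeneAssociation(
            peak_name=peak.name,
            gene_id=gene_id,
            distance=abs(delta),
            signed_distance=signed,
        )
    return associations, unassigned


class _GeneBodyIndex:
    """Point-in-span queries over gene bodies (linear per-chromosome scan
    bounded by sorted starts; gene sets here are small)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.span.start)

    def covering(self, chrom: str, point: int) -> list[GeneModel]:
        return [g for g in self._by_chrom.get(chrom, ())
                if g.span.start <= point < g.span.end]


def annotate_categories(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    associations: Mapping[str, PeakGeneAssociation],
) -> dict[str, AnnotationCategory]:
    """Assign exactly one genomic category per peak.

    Precedence: a summit inside any gene body is EXON (if inside an exon
    of a covering gene) or INTRON; otherwise the closest gene's upstream
    bins apply (<= 2 kb PROXIMAL, <= 10 kb DISTAL, <= 100 kb FIVE_D);
    downstream or farther peaks are OTHER.
    """
    body_index = _GeneBodyIndex(genes)
    out: dict[str, AnnotationCategory] = {}
    for peak in peaks:
        summit = peak.effective_summit
        covering = body_index.covering(peak.chrom, summit)
        if covering:
            in_exon = any(
                e.start <= summit < e.end for g in covering for e in g.exons
            )
            out[peak.name] = AnnotationCategory.EXON if in_exon else AnnotationCategory.INTRON
            continue
        assoc = associations.get(peak.name)
        if assoc is None or assoc.signed_distance >= 0:
            out[peak.name] = AnnotationCategory.OTHER
            continue
        upstream = -assoc.signed_distance
        for category, bound in UPSTREAM_BINS:
            if upstream <= bound:
                out[peak.name] = category
                break
        else:
            out[peak.name] = AnnotationCategory.OTHER
    return out


def tss_distance_profile(
    associations: Iterable[PeakGeneAssociation],
    window: int = 10_000,
    bin_size: int = 1_000,
) -> list[tuple[int, int, int]]:
    """Histogram of signed summit-TSS distances over ``[-window, +window)``.

    Returns (bin_start, bin_end, count) rows in ascending order; an
    association falls in bin ``floor(signed_distance / bin_size)``, and
    distances at exactly +window are excluded (half-open binning).
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin size")
    n_bins_side = window // bin_size
    counts = [0] * (2 * n_bins_side)
    for assoc in associations:
        d = assoc.signed_distance
        if -window <= d < window:
            counts[d // bin_size + n_bins_side] += 1
    return [
        ((i - n_bins_side) * bin_size, (i - n_bins_side + 1) * bin_size, c)
        for i, c in enumerate(counts)
    ]


def expression_correlated_flags(
    associations: Mapping[str, PeakGeneAssociation],
    modulated_genes: set[str],
) -> dict[str, bool]:
    """A peak is expression-correlated iff its closest gene is modulated."""
    return {name: a.gene_id in modulated_genes for name, a in associations.items()}
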