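"""Cross-cell-line peak-set comparison and chromatin-state assignment.

Venn counts are *per reference set*: count(X->Y) is the number of X
peaks overlapping >= 1 Y peak, which is not symmetric (each set's peaks
are counted from its own perspective, matching how peak-set overlaps are
reported in practice).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import ChromatinStateSegment, CORE15_STATES, Peak, any_overlap_flags


@dataclass(frozen=True)
class VennResult:
    size_a: int
    size_b: int
    size_c: int
    a_in_b: int      # A peaks overlapping >= 1 B peak
    a_in_c: int
    b_in_a: int
    b_in_c: int
    c_in_a: int
    c_in_b: int
    a_in_bc: int     # A peaks overlapping both sets
    b_in_ac: int
    c_in_ab: int


def venn_counts(
    a: Sequence[Peak],
    b: Sequence[Peak],
    c: Sequence[Peak] = (),
) -> VennResult:
    """Pairwise and triple overlap counts for three peak sets (>= 1 bp)."""
    def flags(queries, subjects):
        if not queries or not subjects:
            return [False] * len(queries)
        return any_overlap_flags(queries, subjects)

    ab, ac = flags(a, b), flags(a, c)
    ba, bc = flags(b, a), flags(b, c)
    ca, cb = flags(c, a), flags(c, b)
    return VennResult(
        size_a=len(a), size_b=len(b), size_c=len(c),
        a_in_b=sum(ab), a_in_c=sum(ac),
        b_in_a=sum(ba), b_in_c=sum(bc),
        c_in_a=sum(ca), c_in_b=sum(cb),
        a_in_bc=sum(x and y for x, y in zip(ab, ac)),
        b_in_ac=sum(x and y for x, y in zip(ba, bc)),
        c_in_ab=sum(x and y for x, y in zip(ca, cb)),
    )


def percent(count: int, total: int) -> float:
    """100 * count / total at full precision (rounding is display-only)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= count <= total):
        raise ValueError(f"count {count} outside [0, {total}]")
    return 100.0 * count / total


class StateIndex:
    """Sorted per-chromosome chromatin segments for overlap queries."""

    def __init__(self, segments: Sequence[ChromatinStateSegment]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
        per_chrom: dict[str, list[ChromatinStateSegment]] = {}
        for seg in segments:
            per_chrom.setdefault(seg.interval.chrom, []).append(seg)
        for chrom, segs in per_chrom.items():
            segs.sort(key=lambda s: s.interval.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping chromatin segments on {chrom} at "
                        f"{cur.interval.start}"
                    )
            self._by_chrom[chrom] = (
                [s.interval.start for s in segs],
                [s.interval.end for s in segs],
                [s.state for s in segs],
            )

    def overlapping(self, peak: Peak) -> list[tuple[str, int, int, int]]:
        """(state, overlap_bp, seg_start, seg_end) for segments hitting the peak."""
        entry = self._by_chrom.get(peak.chrom)
        if entry is None:
            return []
        starts, ends, states = entry
        s, e = peak.interval.start, peak.interval.end
        lo = bisect_right(ends, s)          # first segment ending after peak start
        hi = bisect_left(starts, e)         # first segment starting at/after peak end
        out = []
        for i in range(lo, hi):
            ov = min(ends[i], e) - max(starts[i], s)
            if ov > 0:
                out.append((states[i], ov, starts[i], ends[i]))
        return out


def assign_state(
    peak: Peak,
    index: StateIndex,
    fallback: str = "Quies",
) -> tuple[str, bool]:
    """The chromatin state with maximal bp overlap with the peak.

    Ties go to the state whose segment covers the effective summit; a
    peak overlapping no segment at all falls back to ``fallback`` and the
    second element of the result flags that case (callers keep a warning
    counter).
    """
    hits = index.overlapping(peak)
    if not hits:
        return fallback, True
    per_state: dict[str, int] = {}
    for state, ov, _, _ in hits:
        per_state[state] = per_state.get(state, 0) + ov
    best = max(per_state.values())
    tied = sorted(s for s, v in per_state.items() if v == best)
    if len(tied) > 1:
        summit = peak.effective_summit
        for state, _, seg_s, seg_e in hits:
            if state in tied and seg_s <= summit < seg_e:
                return state, False
    return tied[0], False


def assign_states(
    peaks: Sequence[Peak],
    segments: Sequence[ChromatinStateSegment],
) -> tuple[dict[str, str], int]:
    """State per peak plus the count of no-overlap fallbacks."""
    index = StateIndex(segments)
    out: dict[str, str] = {}
    n_fallback = 0
    for peak in peaks:
        state, fell_back = assign_state(peak, index)
        out[peak.name] = state
        n_fallback += fell_back
    return out, n_fallback


def state_distribution(
    states: Mapping[str, str],
    subsets: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, float]]:
    """Per-subset fraction of peaks in each of the 15 states.

    ``subsets`` maps a label (e.g. "all", "shared", "specific") to peak
    names; fractions over the fixed state vocabulary sum to 1 for any
    non-empty subset.
    """
    out: dict[str, dict[str, float]] = {}
    for label, names in subsets.items():
        counts = {state: 0 for state in CORE15_STATES}
        for name in names:
            counts[states[name]] += 1
        total = len(names)
        out[label] = {
            state: (counts[state] / total if total else float("nan"))
            for state in CORE15_STATES
        }
    return out


def shared_specific_partition(
    peaks: Sequence[Peak],
    reference: Sequence[Peak],
) -> tuple[list[str], list[str]]:
    """Split peaks into (shared, specific) by >= 1 bp overlap with the
    reference set's peaks."""
    flags = any_overlap_flags(peaks, reference) if reference else [False] * len(peaks)
    shared = [p.name for p, f in zip(peaks, flags) if f]
    specific = [p.name for p, f in zip(peaks, flags) if not f]
    return shared, specific
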