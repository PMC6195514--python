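#!/usr/bin/env python
"""QC-filter the raw peak calls and annotate them against the gene models.

Drops peaks above the fold-enrichment cap (artifact-like pileups), below
the q-value cutoff, or overlapping the blacklist; associates the
survivors to their closest TSS; assigns genomic categories; and writes
the +/- 10 kb TSS distance profile.
"""

from pathlib import Path

from peakcalibre import io
from peakcalibre.peaks import (
    annotate_categories,
    associate_closest_tss,
    filter_peaks,
    tss_distance_profile,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
WS = RESULTS.parent / "scratch" / "workspace"
SCRATCH = RESULTS.parent / "scratch"


def main() -> None:
    peaks = io.parse_narrowpeak(WS / "peaks.narrowPeak")
    blacklist = io.parse_bed3(WS / "blacklist.bed")
    genes = io.parse_gene_table(WS / "genes.tsv")

    result = filter_peaks(peaks, blacklist)
    print(f"filter: {len(peaks)} in, {len(result.retained)} retained, "
          f"rejections {result.reason_counts}")
    io.write_narrowpeak(SCRATCH / "filtered_peaks.narrowPeak", result.retained)

    associations, unassigned = associate_closest_tss(result.retained, genes)
    categories = annotate_categories(result.retained, genes, associations)
    io.write_tsv_report(
        SCRATCH / "peak_annotation.tsv",
        ({"peak": p.name, "gene": associations[p.name].gene_id,
          "distance": associations[p.name].distance,
          "signed_distance": associations[p.name].signed_distance,
          "category": categories[p.name].value}
         for p in result.retained if p.name in associations),
        ["peak", "gene", "distance", "signed_distance", "category"])

    counts: dict[str, int] = {}
    for c in categories.values():
        counts[c.value] = counts.get(c.value, 0) + 1
    total = len(result.retained)
    print("genomic categories:")
    for name, n in sorted(counts.items(), key=lambda kv: -kv[1]):
        print(f"  {name:<9} {n:5d}  ({100 * n / total:.1f}%)")

    profile = tss_distance_profile(associations.values())
    io.write_tsv_report(RESULTS / "tss_profile.tsv",
                        ({"bin_start": s, "bin_end": e, "count": c}
                         for s, e, c in profile),
                        ["bin_start", "bin_end", "count"])
    near = sum(c for _, _, c in profile)
    print(f"{near} of {total} peaks ({100 * near / total:.1f}%) lie within "
          f"+/- 10 kb of a TSS")


if __name__ == "__main__":
    main()
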