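#!/usr/bin/env python
"""Scan peak sequences for ETS / RUNX / IRF motifs and analyse the classes.

Classifies every QC-passing peak by the presence of ETS and RUNX motif
hits, reports the class composition and its dependence on the
fold-enrichment threshold, tests whether ETS-containing peaks are
stronger (pooled two-sample t), and counts ETS-IRF compound motifs among
the motif-free peaks.
"""

from pathlib import Path

from peakcalibre import io
from peakcalibre.calibration import default_grid
from peakcalibre.motifs import (
    PeakMotifClass,
    class_fraction_curve,
    classify_peaks,
    compound_motif_report,
    group_fe_test,
    scan_peak_sequences,
)
from peakcalibre.peaks import (
    associate_closest_tss,
    expression_correlated_flags,
    filter_peaks,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
WS = RESULTS.parent / "scratch" / "workspace"
SCRATCH = RESULTS.parent / "scratch"


def main() -> None:
    peaks = filter_peaks(io.parse_narrowpeak(WS / "peaks.narrowPeak"),
                         io.parse_bed3(WS / "blacklist.bed")).retained
    seqs = io.parse_fasta(WS / "peak_sequences.fa")
    seqs = {p.name: seqs[p.name] for p in peaks}
    pwms = io.parse_pwm_text(WS / "pwms.txt")

    hits = scan_peak_sequences(seqs, pwms)
    classes = classify_peaks(seqs, hits, pwms)
    counts: dict[str, int] = {c.value: 0 for c in PeakMotifClass}
    for c in classes.values():
        counts[c.motif_class.value] += 1
    total = len(peaks)
    print("motif classes:")
    for name, n in counts.items():
        print(f"  {name:<10} {n:5d}  ({100 * n / total:.1f}%)")
    io.write_tsv_report(
        SCRATCH / "motif_classes.tsv",
        ({"peak": name, "motif_class": c.motif_class.value,
          "has_ets_irf_compound": int(c.has_ets_irf_compound)}
         for name, c in classes.items()),
        ["peak", "motif_class", "has_ets_irf_compound"])

    curve = class_fraction_curve(peaks, classes, default_grid())
    io.write_tsv_report(
        RESULTS / "class_fraction_curve.tsv",
        ({"threshold": f"{r['threshold']:.1f}", "n_peaks": r["n_peaks"],
          **{c.value: f"{r[c.value]:.4f}" for c in PeakMotifClass}}
         for r in curve),
        ["threshold", "n_peaks"] + [c.value for c in PeakMotifClass])
    first, last = curve[0], curve[-1]
    print(f"ETS-containing fraction rises from "
          f"{first['ETS_ONLY'] + first['ETS_RUNX']:.2f} at FE>=3.0 to "
          f"{last['ETS_ONLY'] + last['ETS_RUNX']:.2f} at FE>=7.0")

    fe = {c.value: [] for c in PeakMotifClass}
    for p in peaks:
        fe[classes[p.name].motif_class.value].append(p.fold_enrichment)
    test = group_fe_test(fe["ETS_ONLY"] + fe["ETS_RUNX"], fe["NEITHER"])
    print(f"ETS-containing vs motif-free fold enrichment: "
          f"t={test.t_statistic:.2f}, p={test.p_value:.2e} "
          f"(means {test.mean_a:.2f} vs {test.mean_b:.2f})")

    genes = io.parse_gene_table(WS / "genes.tsv")
    up, down = io.parse_gene_list(WS / "modulated_genes.tsv")
    assoc, _ = associate_closest_tss(peaks, genes)
    corr = expression_correlated_flags(assoc, up | down)
    compound = compound_motif_report(classes, hits, pwms, corr)
    print(f"{compound['n_neither_with_compound']} of {compound['n_neither']} "
          f"motif-free peaks carry the ETS-IRF compound motif "
          f"({compound['n_corr_neither_with_compound']} of "
          f"{compound['n_neither_expression_correlated']} expression-correlated)")


if __name__ == "__main__":
    main()
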