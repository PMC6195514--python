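#!/usr/bin/env python
"""Compare the prioritized peaks with the two companion peak sets and
assign chromatin states.

Reports per-reference-set Venn counts (each set's peaks counted from its
own perspective) and the 15-state chromatin distribution for all, shared
and set-specific peaks — on this workspace the shared peaks were planted
into TSS-flanking/enhancer states and the specific peaks onto the
quiescent background.
"""

from pathlib import Path

from peakcalibre import io
from peakcalibre.comparative import (
    assign_states,
    percent,
    shared_specific_partition,
    state_distribution,
    venn_counts,
)
from peakcalibre.peaks import filter_peaks

RESULTS = Path(__file__).resolve().parent.parent / "results"
WS = RESULTS.parent / "scratch" / "workspace"


def main() -> None:
    peaks = filter_peaks(io.parse_narrowpeak(WS / "peaks.narrowPeak"),
                         io.parse_bed3(WS / "blacklist.bed")).retained
    set_b = io.parse_narrowpeak(WS / "companion_b.narrowPeak")
    set_c = io.parse_narrowpeak(WS / "companion_c.narrowPeak")

    v = venn_counts(peaks, set_b, set_c)
    print(f"A={v.size_a}, B={v.size_b}, C={v.size_c}")
    print(f"A peaks shared with B: {v.a_in_b} "
          f"({percent(v.a_in_b, v.size_a):.2f}%)")
    print(f"A peaks shared with C: {v.a_in_c} "
          f"({percent(v.a_in_c, v.size_a):.2f}%)")
    print(f"A peaks shared with both: {v.a_in_bc} "
          f"({percent(v.a_in_bc, v.size_a):.2f}%)")
    io.write_tsv_report(
        RESULTS / "venn.tsv",
        [{"quantity": k, "count": n} for k, n in (
            ("A", v.size_a), ("B", v.size_b), ("C", v.size_c),
            ("A_in_B", v.a_in_b), ("A_in_C", v.a_in_c),
            ("B_in_A", v.b_in_a), ("B_in_C", v.b_in_c),
            ("C_in_A", v.c_in_a), ("C_in_B", v.c_in_b),
            ("A_in_BC", v.a_in_bc))],
        ["quantity", "count"])

    segments = io.parse_states_bed(WS / "states.bed")
    states, _ = assign_states(peaks, segments)
    shared, specific = shared_specific_partition(peaks, set_b)
    dist = state_distribution(states, {
        "all": [p.name for p in peaks], "shared": shared, "specific": specific})
    io.write_tsv_report(
        RESULTS / "state_distribution.tsv",
        ({"subset": label, "state": s, "fraction": f"{frac:.4f}"}
         for label, per_state in dist.items() for s, frac in per_state.items()),
        ["subset", "state", "fraction"])
    sizes = {"all": len(peaks), "shared": len(shared), "specific": len(specific)}
    for label in ("all", "shared", "specific"):
        top = sorted(dist[label].items(), key=lambda kv: -kv[1])[:3]
        pretty = ", ".join(f"{s} {100 * f:.0f}%" for s, f in top)
        print(f"chromatin states ({label}, n={sizes[label]}): {pretty}")


if __name__ == "__main__":
    main()
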