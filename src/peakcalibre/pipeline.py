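"""End-to-end pipeline: filter -> associate -> calibrate -> annotate ->
compare -> motif analysis, with TSV outputs and a machine-readable
summary.

Every stage is a pure function of (inputs, config, seed); rerunning the
pipeline on the same workspace and configuration produces byte-identical
outputs.  A verification pass re-derives the summary counts from the
stage TSVs and fails loudly on any mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration as cal
from . import comparative, io, motifs, peaks as pk
from .core import chromosome_name_mismatches


class PipelineError(RuntimeError):
    """A stage failure, naming the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_CONFIG_KEYS = {
    "peaks", "blacklist", "genes", "modulated_genes", "universe_size",
    "states", "companion_b", "companion_c", "peak_sequences", "pwms",
    "fe_cap", "q_max", "grid_min", "grid_max", "grid_step", "sidedness",
    "motif_frac_threshold", "profile_window", "profile_bin",
    "summit_window", "summit_bin", "enrichment_shuffles", "seed",
}


@dataclass
class PipelineConfig:
    """Input paths and stage parameters (see the config-file keys of the
    same names)."""

    peaks: Path
    genes: Path
    modulated_genes: Path
    blacklist: Path | None = None
    states: Path | None = None
    companion_b: Path | None = None
    companion_c: Path | None = None
    peak_sequences: Path | None = None
    pwms: Path | None = None
    universe_size: int | None = None     # default: number of genes in `genes`
    fe_cap: float = 50.0
    q_max: float = 0.1
    grid_min: float = 3.0
    grid_max: float = 7.0
    grid_step: float = 0.1
    sidedness: str = "greater"           # or "two-sided"
    motif_frac_threshold: float = 0.8
    profile_window: int = 10_000
    profile_bin: int = 1_000
    summit_window: int = 500
    summit_bin: int = 50
    enrichment_shuffles: int = 0         # shuffle-based motif enrichment off by default
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        for key in ("peaks", "genes", "modulated_genes", "blacklist", "states",
                    "companion_b", "companion_c", "peak_sequences", "pwms"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def grid(self) -> list[float]:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        grid = [round(self.grid_min + i * self.grid_step, 10) for i in range(n + 1)]
        if not grid:
            raise PipelineError("config", "empty calibration grid")
        return grid


@dataclass
class PipelineReport:
    summary: dict
    outdir: Path
    calibration: cal.CalibrationResult | None = None
    log_lines: list[str] = field(default_factory=list)


def _require(config: PipelineConfig, attr: str, stage: str) -> Path:
    path = getattr(config, attr)
    if path is None:
        raise PipelineError(stage, f"config key '{attr}' is required for this stage")
    if not Path(path).exists():
        raise PipelineError(stage, f"input path does not exist: {path}")
    return Path(path)


def run_all(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Execute the full analysis sequence and write the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pipeline seed={config.seed}"]
    summary: dict = {"parameters": {
        "fe_cap": config.fe_cap, "q_max": config.q_max,
        "grid": [config.grid_min, config.grid_max, config.grid_step],
        "sidedness": config.sidedness,
        "motif_frac_threshold": config.motif_frac_threshold,
        "seed": config.seed,
    }}

    # --- load & filter ----------------------------------------------------
    all_peaks = io.parse_narrowpeak(_require(config, "peaks", "filter"))
    blacklist = (io.parse_bed3(_require(config, "blacklist", "filter"))
                 if config.blacklist else [])
    genes = io.parse_gene_table(_require(config, "genes", "associate"))
    only_p, only_g = chromosome_name_mismatches(
        (p.chrom for p in all_peaks), (g.chrom for g in genes))
    if only_p or only_g:
        log.append(f"WARNING chromosome name mismatch: peaks-only={sorted(only_p)} "
                   f"genes-only={sorted(only_g)}")
    filt = pk.filter_peaks(all_peaks, blacklist,
                           fe_cap=config.fe_cap, q_max=config.q_max)
    io.write_narrowpeak(outdir / "filtered_peaks.narrowPeak", filt.retained)
    log.append(f"filter in={len(all_peaks)} retained={len(filt.retained)} "
               f"rejected={dict(sorted(filt.reason_counts.items()))}")
    summary["filter"] = {"input": len(all_peaks), "retained": len(filt.retained),
                         "rejections": filt.reason_counts}

    # --- associate & calibrate -------------------------------------------
    up, down = io.parse_gene_list(_require(config, "modulated_genes", "calibrate"))
    if not (up or down):
        raise PipelineError("calibrate", "modulated gene list is empty")
    universe = config.universe_size or len(genes)
    expr = cal.ExpressionModulationSet(frozenset(up), frozenset(down), universe)
    associations, unassigned = pk.associate_closest_tss(filt.retained, genes)
    if unassigned:
        log.append(f"WARNING {len(unassigned)} peaks on chromosomes without genes")
    result = cal.sweep_thresholds(
        filt.retained, associations, expr, grid=config.grid(),
        two_sided=(config.sidedness == "two-sided"))
    io.write_tsv_report(
        outdir / "calibration.tsv",
        ({"threshold": f"{r.threshold:.1f}", "n_peaks": r.n_peaks,
          "n_genes": r.n_genes, "n_mod_overlap": r.n_mod_overlap,
          "pct_mod": f"{r.pct_mod:.6g}", "pct_all": f"{r.pct_all:.6g}",
          "enrichment_ratio": f"{r.enrichment_ratio:.6g}",
          "fisher_p": f"{r.fisher_p:.6g}",
          "selected": int(r.threshold == result.selected_threshold)}
         for r in result.rows),
        ["threshold", "n_peaks", "n_genes", "n_mod_overlap", "pct_mod",
         "pct_all", "enrichment_ratio", "fisher_p", "selected"])
    t_star = result.selected_threshold
    sel_row = result.selected_row
    log.append(f"calibrate selected_threshold={t_star} "
               f"fisher_p={sel_row.fisher_p:.3e}")
    summary["calibration"] = {
        "selected_threshold": t_star,
        "n_peaks_at_selected": sel_row.n_peaks,
        "n_genes_at_selected": sel_row.n_genes,
        "n_mod_overlap_at_selected": sel_row.n_mod_overlap,
        "pct_mod": sel_row.pct_mod, "pct_all": sel_row.pct_all,
        "enrichment_ratio": sel_row.enrichment_ratio,
        "fisher_p": sel_row.fisher_p,
    }

    # --- restrict & annotate ---------------------------------------------
    prioritized = [p for p in filt.retained if p.fold_enrichment >= t_star]
    categories = pk.annotate_categories(prioritized, genes, associations)
    modulated = expr.modulated
    corr = pk.expression_correlated_flags(
        {n: a for n, a in associations.items()
         if n in {p.name for p in prioritized}}, set(modulated))
    assoc_rows = []
    for peak in prioritized:
        a = associations.get(peak.name)
        assoc_rows.append({
            "peak": peak.name,
            "fold_enrichment": f"{peak.fold_enrichment:.6g}",
            "gene": a.gene_id if a else "",
            "distance": a.distance if a else "",
            "signed_distance": a.signed_distance if a else "",
            "category": categories[peak.name].value,
            "expression_correlated": int(corr.get(peak.name, False)),
        })
    io.write_tsv_report(outdir / "associations.tsv", assoc_rows,
                        ["peak", "fold_enrichment", "gene", "distance",
                         "signed_distance", "category", "expression_correlated"])
    cat_counts = {c.value: 0 for c in pk.AnnotationCategory}
    for v in categories.values():
        cat_counts[v.value] += 1
    profile = pk.tss_distance_profile(
        [associations[p.name] for p in prioritized if p.name in associations],
        window=config.profile_window, bin_size=config.profile_bin)
    io.write_tsv_report(outdir / "tss_profile.tsv",
                        ({"bin_start": s, "bin_end": e, "count": c}
                         for s, e, c in profile),
                        ["bin_start", "bin_end", "count"])
    n_corr = sum(corr.values())
    summary["annotation"] = {
        "n_prioritized": len(prioritized),
        "categories": cat_counts,
        "n_expression_correlated": n_corr,
        "n_in_tss_window": sum(c for _, _, c in profile),
    }
    log.append(f"annotate prioritized={len(prioritized)} "
               f"expression_correlated={n_corr}")

    # --- compare (venn + chromatin states) --------------------------------
    if config.companion_b and config.companion_c:
        set_b = io.parse_narrowpeak(_require(config, "companion_b", "compare"))
        set_c = io.parse_narrowpeak(_require(config, "companion_c", "compare"))
        venn = comparative.venn_counts(prioritized, set_b, set_c)
        io.write_tsv_report(
            outdir / "venn.tsv",
            [{"quantity": k, "count": v, "pct_of_reference": f"{p:.6g}"}
             for k, v, p in [
                 ("A", venn.size_a, 100.0), ("B", venn.size_b, 100.0),
                 ("C", venn.size_c, 100.0),
                 ("A_in_B", venn.a_in_b, comparative.percent(venn.a_in_b, venn.size_a)),
                 ("A_in_C", venn.a_in_c, comparative.percent(venn.a_in_c, venn.size_a)),
                 ("B_in_A", venn.b_in_a, comparative.percent(venn.b_in_a, venn.size_b)),
                 ("B_in_C", venn.b_in_c, comparative.percent(venn.b_in_c, venn.size_b)),
                 ("C_in_A", venn.c_in_a, comparative.percent(venn.c_in_a, venn.size_c)),
                 ("C_in_B", venn.c_in_b, comparative.percent(venn.c_in_b, venn.size_c)),
                 ("A_in_BC", venn.a_in_bc, comparative.percent(venn.a_in_bc, venn.size_a)),
                 ("B_in_AC", venn.b_in_ac, comparative.percent(venn.b_in_ac, venn.size_b)),
                 ("C_in_AB", venn.c_in_ab, comparative.percent(venn.c_in_ab, venn.size_c)),
             ]],
            ["quantity", "count", "pct_of_reference"])
        summary["venn"] = {
            "size_a": venn.size_a, "size_b": venn.size_b, "size_c": venn.size_c,
            "a_in_b": venn.a_in_b, "a_in_c": venn.a_in_c,
            "a_in_bc": venn.a_in_bc,
            "pct_a_in_b": comparative.percent(venn.a_in_b, venn.size_a),
            "pct_a_in_c": comparative.percent(venn.a_in_c, venn.size_a),
            "pct_a_in_bc": comparative.percent(venn.a_in_bc, venn.size_a),
        }
        shared, specific = comparative.shared_specific_partition(prioritized, set_b)
        log.append(f"compare shared={len(shared)} specific={len(specific)}")
    else:
        shared, specific = [], [p.name for p in prioritized]

    if config.states:
        segments = io.parse_states_bed(_require(config, "states", "compare"))
        states, n_fallback = comparative.assign_states(prioritized, segments)
        if n_fallback:
            log.append(f"WARNING {n_fallback} peaks overlapped no chromatin segment")
        io.write_tsv_report(outdir / "peak_states.tsv",
                            ({"peak": p.name, "state": states[p.name]}
                             for p in prioritized),
                            ["peak", "state"])
        subsets = {"all": [p.name for p in prioritized]}
        if shared or (config.companion_b and config.companion_c):
            subsets["shared"] = shared
            subsets["specific"] = specific
        dist = comparative.state_distribution(states, subsets)
        rows = [{"subset": label, "state": s, "fraction": f"{frac:.6g}"}
                for label, per_state in dist.items()
                for s, frac in per_state.items()]
        io.write_tsv_report(outdir / "state_distribution.tsv", rows,
                            ["subset", "state", "fraction"])
        summary["states"] = {
            label: {s: per_state[s] for s in
                    sorted(per_state, key=per_state.get, reverse=True)[:3]}
            for label, per_state in dist.items()
        }

    # --- motif analysis ----------------------------------------------------
    if config.peak_sequences and config.pwms:
        seqs = io.parse_fasta(_require(config, "peak_sequences", "motifs"))
        pwm_list = io.parse_pwm_text(_require(config, "pwms", "motifs"))
        missing = [p.name for p in prioritized if p.name not in seqs]
        if missing:
            raise PipelineError("motifs",
                                f"no sequence for peaks: {missing[:5]}")
        seqs = {p.name: seqs[p.name] for p in prioritized}
        hits = motifs.scan_peak_sequences(
            seqs, pwm_list, frac_threshold=config.motif_frac_threshold)
        classes = motifs.classify_peaks(seqs, hits, pwm_list)
        io.write_tsv_report(
            outdir / "motif_hits.tsv",
            ({"peak": h.peak_name, "pwm": h.pwm_id, "offset": h.offset,
              "strand": h.strand, "score": f"{h.score:.4f}"} for h in hits),
            ["peak", "pwm", "offset", "strand", "score"])
        io.write_tsv_report(
            outdir / "motif_classes.tsv",
            ({"peak": name, "motif_class": c.motif_class.value,
              "has_ets_irf_compound": int(c.has_ets_irf_compound)}
             for name, c in classes.items()),
            ["peak", "motif_class", "has_ets_irf_compound"])
        class_counts = {c.value: 0 for c in motifs.PeakMotifClass}
        for c in classes.values():
            class_counts[c.motif_class.value] += 1
        summary["motifs"] = {"classes": class_counts}
        log.append(f"motifs classes={class_counts}")

        curve = motifs.class_fraction_curve(prioritized, classes, config.grid())
        io.write_tsv_report(
            outdir / "class_fraction_curve.tsv",
            ({"threshold": f"{r['threshold']:.1f}", "n_peaks": r["n_peaks"],
              **{c.value: f"{r[c.value]:.6g}" for c in motifs.PeakMotifClass}}
             for r in curve),
            ["threshold", "n_peaks"] + [c.value for c in motifs.PeakMotifClass])

        peak_by_name = {p.name: p for p in prioritized}
        profile_by_family = motifs.summit_centering_profile(
            hits, peak_by_name, pwm_list,
            window=config.summit_window, bin_size=config.summit_bin)
        io.write_tsv_report(
            outdir / "summit_profile.tsv",
            ({"family": fam, "bin_start": s, "bin_end": e, "count": c}
             for fam in sorted(profile_by_family)
             for s, e, c in profile_by_family[fam]),
            ["family", "bin_start", "bin_end", "count"])

        fe_by_class: dict[str, list[float]] = {c.value: [] for c in motifs.PeakMotifClass}
        for p in prioritized:
            fe_by_class[classes[p.name].motif_class.value].append(p.fold_enrichment)
        ets_containing = fe_by_class["ETS_ONLY"] + fe_by_class["ETS_RUNX"]
        test_rows = []
        for label, ga, gb in (
            ("ETS_containing_vs_NEITHER", ets_containing, fe_by_class["NEITHER"]),
            ("ETS_containing_vs_RUNX_ONLY", ets_containing, fe_by_class["RUNX_ONLY"]),
            ("ETS_ONLY_vs_RUNX_ONLY", fe_by_class["ETS_ONLY"], fe_by_class["RUNX_ONLY"]),
        ):
            if len(ga) >= 2 and len(gb) >= 2:
                r = motifs.group_fe_test(ga, gb)
                test_rows.append({
                    "comparison": label, "n_a": len(ga), "n_b": len(gb),
                    "t": f"{r.t_statistic:.4f}", "p": f"{r.p_value:.4g}",
                    "mean_a": f"{r.mean_a:.4f}", "mean_b": f"{r.mean_b:.4f}",
                    "a_p5": f"{r.summary_a[0]:.4f}", "a_median": f"{r.summary_a[1]:.4f}",
                    "a_p95": f"{r.summary_a[2]:.4f}",
                    "b_p5": f"{r.summary_b[0]:.4f}", "b_median": f"{r.summary_b[1]:.4f}",
                    "b_p95": f"{r.summary_b[2]:.4f}",
                })
        io.write_tsv_report(outdir / "group_tests.tsv", test_rows,
                            ["comparison", "n_a", "n_b", "t", "p", "mean_a",
                             "mean_b", "a_p5", "a_median", "a_p95", "b_p5",
                             "b_median", "b_p95"])
        summary["group_tests"] = {
            row["comparison"]: {"t": float(row["t"]), "p": float(row["p"])}
            for row in test_rows
        }

        compound = motifs.compound_motif_report(classes, hits, pwm_list, corr)
        summary["compound_motif"] = compound

        if config.enrichment_shuffles > 0:
            enr_rows = []
            for pwm in pwm_list:
                e = motifs.shuffle_enrichment(
                    seqs, pwm, n_shuffles=config.enrichment_shuffles,
                    frac_threshold=config.motif_frac_threshold, seed=config.seed)
                enr_rows.append({"pwm": pwm.id, "family": pwm.family,
                                 **{k: f"{v:.6g}" for k, v in e.items()}})
            io.write_tsv_report(outdir / "motif_enrichment.tsv", enr_rows,
                                ["pwm", "family", "observed_fraction",
                                 "shuffled_fraction", "enrichment", "empirical_p"])

    # --- report ------------------------------------------------------------
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    _verify_summary(outdir, summary)
    return PipelineReport(summary=summary, outdir=outdir,
                          calibration=result, log_lines=log)


def _verify_summary(outdir: Path, summary: dict) -> None:
    """Re-derive headline counts from the stage TSVs; mismatch -> error."""
    assoc = pd.read_csv(outdir / "associations.tsv", sep="\t")
    if len(assoc) != summary["annotation"]["n_prioritized"]:
        raise PipelineError("verify", "association row count != summary")
    cat = assoc["category"].value_counts().to_dict()
    for name, count in summary["annotation"]["categories"].items():
        if cat.get(name, 0) != count:
            raise PipelineError("verify", f"category count mismatch for {name}")
    if int(assoc["expression_correlated"].sum()) != \
            summary["annotation"]["n_expression_correlated"]:
        raise PipelineError("verify", "expression-correlated count mismatch")
    calib = pd.read_csv(outdir / "calibration.tsv", sep="\t")
    sel = calib.loc[calib["selected"] == 1, "threshold"]
    if len(sel) != 1 or float(sel.iloc[0]) != summary["calibration"]["selected_threshold"]:
        raise PipelineError("verify", "selected threshold mismatch")
    if (outdir / "motif_classes.tsv").exists():
        mc = pd.read_csv(outdir / "motif_classes.tsv", sep="\t")
        counts = mc["motif_class"].value_counts().to_dict()
        for name, count in summary["motifs"]["classes"].items():
            if counts.get(name, 0) != count:
                raise PipelineError("verify", f"motif class count mismatch for {name}")
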