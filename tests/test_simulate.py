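"""Synthetic-data generator: determinism, planted structure, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peakcalibre import io
from peakcalibre.calibration import ExpressionModulationSet, sweep_thresholds
from peakcalibre.motifs import group_fe_test
from peakcalibre.peaks import associate_closest_tss
from peakcalibre.simulate import (
    SyntheticConfig,
    extract_peak_sequences,
    generate_companion_sets,
    generate_expression,
    generate_genes,
    generate_genome,
    generate_peaks,
    generate_states,
    generate_workspace,
)


SMALL = SyntheticConfig(seed=5, n_peaks=300)


class TestConfigValidation:
    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="priors"):
            SyntheticConfig(class_priors=(0.5, 0.5, 0.5, 0.5))

    def test_boosted_rate_must_exceed_base(self):
        with pytest.raises(ValueError, match="boosted"):
            SyntheticConfig(base_rate=0.5, boosted_rate=0.1)

    def test_triple_overlap_bounded_by_pairwise(self):
        with pytest.raises(ValueError, match="p_abc"):
            SyntheticConfig(p_ab=0.1, p_ac=0.1, p_abc=0.2)


class TestGenome:
    def test_deterministic_and_correct_shape(self):
        cfg = SyntheticConfig(seed=3, n_chroms=2, chrom_length=50_000)
        g1 = generate_genome(cfg)
        g2 = generate_genome(cfg)
        assert list(g1) == ["chr1", "chr2"]
        assert all(len(s) == 50_000 for s in g1.values())
        assert g1 == g2

    def test_base_composition_near_uniform(self):
        cfg = SyntheticConfig(seed=4, n_chroms=1, chrom_length=1_000_000)
        seq = bytes(generate_genome(cfg)["chr1"])
        n = len(seq)
        # binomial CI: p=0.25, sd = sqrt(p(1-p)/n) ~ 4.3e-4; allow 5 sd
        for base in b"ACGT":
            frac = seq.count(base) / n
            assert abs(frac - 0.25) < 5 * np.sqrt(0.25 * 0.75 / n)


class TestGenes:
    def test_count_and_invariants(self):
        genes = generate_genes(SMALL)
        assert len(genes) == SMALL.n_genes
        for g in genes[:200]:
            assert g.span.start <= g.tss < g.span.end
            for e in g.exons:
                assert g.span.start <= e.start < e.end <= g.span.end

    def test_tss_positions_roughly_uniform(self):
        genes = generate_genes(SMALL)
        tss = np.array([g.tss for g in genes if g.chrom == "chr1"])
        stat, p = stats.kstest(tss / SMALL.chrom_length, "uniform")
        assert p > 1e-4


class TestPeaks:
    def test_class_counts_within_binomial_ci(self):
        cfg = SyntheticConfig(seed=6, n_peaks=2_000)
        _, truth = generate_peaks(cfg, None)
        counts = truth["motif_class"].value_counts()
        for cls, prior in zip(("ETS_ONLY", "RUNX_ONLY", "ETS_RUNX", "NEITHER"),
                              cfg.class_priors):
            sd = np.sqrt(prior * (1 - prior) * cfg.n_peaks)
            assert abs(counts[cls] - prior * cfg.n_peaks) < 5 * sd

    def test_no_motifs_planted_when_all_neither(self):
        cfg = SyntheticConfig(seed=7, n_peaks=100,
                              class_priors=(0.0, 0.0, 0.0, 1.0),
                              compound_in_neither=0.0)
        genome = generate_genome(cfg)
        pristine = {c: bytes(s) for c, s in genome.items()}
        _, truth = generate_peaks(cfg, genome)
        assert (truth["planted_families"] == "").all()
        assert {c: bytes(s) for c, s in genome.items()} == pristine

    def test_ets_classes_have_greater_mean_fe(self):
        cfg = SyntheticConfig(seed=8, n_peaks=2_000)
        _, truth = generate_peaks(cfg, None)
        ets = truth.loc[truth["motif_class"].isin(["ETS_ONLY", "ETS_RUNX"]),
                        "fold_enrichment"]
        neither = truth.loc[truth["motif_class"] == "NEITHER", "fold_enrichment"]
        result = group_fe_test(ets, neither)
        assert result.mean_a > result.mean_b
        assert result.p_value < 0.01

    def test_planted_motifs_sit_inside_their_peaks(self):
        genome = generate_genome(SMALL)
        peaks, truth = generate_peaks(SMALL, genome)
        seqs = extract_peak_sequences(genome, peaks)
        from peakcalibre.motifs import builtin_pwms, reverse_complement
        consensus = {p.family: p.consensus for p in builtin_pwms()}
        checked = 0
        for row in truth.itertuples():
            if not row.planted_families:
                continue
            seq = seqs[row.name]
            for fam, off in zip(row.planted_families.split(","),
                                str(row.planted_offsets).split(",")):
                motif = consensus[fam]
                window = seq[int(off):int(off) + len(motif)]
                assert window in (motif, reverse_complement(motif))
                checked += 1
        assert checked > 100


class TestExpressionCoupling:
    def test_up_down_disjoint(self):
        genes = generate_genes(SMALL)
        peaks, _ = generate_peaks(SMALL, None)
        up, down = generate_expression(SMALL, peaks, genes)
        assert not up & down
        assert up and down

    def test_null_coupling_has_no_recoverable_structure(self):
        # boosted == base is disallowed by validation; use a negligible gap
        cfg = SyntheticConfig(seed=9, n_peaks=1_000, base_rate=0.05,
                              boosted_rate=0.0500001)
        genes = generate_genes(cfg)
        peaks, _ = generate_peaks(cfg, None)
        up, down = generate_expression(cfg, peaks, genes)
        assoc, _ = associate_closest_tss(peaks, genes)
        fe_best = {}
        for name, a in assoc.items():
            fe = next(p.fold_enrichment for p in peaks if p.name == name)
            fe_best[a.gene_id] = max(fe_best.get(a.gene_id, 0), fe)
        eligible = {g for g, fe in fe_best.items() if fe >= cfg.coupling_t0}
        mod = up | down
        # modulation rate of strong-peak genes matches the base rate
        rate = len(mod & eligible) / len(eligible)
        sd = np.sqrt(0.05 * 0.95 / len(eligible))
        assert abs(rate - 0.05) < 5 * sd

    def test_planted_threshold_recovered_by_sweep(self):
        cfg = SyntheticConfig(seed=10, n_peaks=2_000)
        genes = generate_genes(cfg)
        peaks, _ = generate_peaks(cfg, None)
        up, down = generate_expression(cfg, peaks, genes)
        expr = ExpressionModulationSet(frozenset(up), frozenset(down), cfg.n_genes)
        assoc, _ = associate_closest_tss(peaks, genes)
        result = sweep_thresholds(peaks, assoc, expr)
        assert abs(result.selected_threshold - cfg.coupling_t0) <= 0.3


class TestCompanionSets:
    def test_zero_probability_gives_zero_overlap(self):
        cfg = SyntheticConfig(seed=11, n_peaks=200, p_ab=0.0, p_ac=0.0, p_abc=0.0,
                              companion_sizes=(300, 300))
        peaks, _ = generate_peaks(cfg, None)
        set_b, set_c, shared = generate_companion_sets(cfg, peaks)
        from peakcalibre.comparative import venn_counts
        v = venn_counts(peaks, set_b, set_c)
        assert v.a_in_b == 0 and v.a_in_c == 0
        assert not shared["in_b"].any()

    def test_recovered_overlap_matches_planted_fraction(self):
        cfg = SyntheticConfig(seed=12, n_peaks=2_000)
        peaks, _ = generate_peaks(cfg, None)
        set_b, set_c, _ = generate_companion_sets(cfg, peaks)
        from peakcalibre.comparative import venn_counts
        v = venn_counts(peaks, set_b, set_c)
        for observed, p in ((v.a_in_b, cfg.p_ab), (v.a_in_c, cfg.p_ac),
                            (v.a_in_bc, cfg.p_abc)):
            sd = np.sqrt(p * (1 - p) * cfg.n_peaks)
            assert abs(observed - p * cfg.n_peaks) < 5 * sd

    def test_same_seed_identical_output(self):
        peaks, _ = generate_peaks(SMALL, None)
        b1, c1, s1 = generate_companion_sets(SMALL, peaks)
        b2, c2, s2 = generate_companion_sets(SMALL, peaks)
        assert b1 == b2 and c1 == c2
        assert s1.equals(s2)


class TestStates:
    def test_full_bias_labels_every_shared_peak_active(self):
        cfg = SyntheticConfig(seed=13, n_peaks=200, state_bias_shared=1.0)
        peaks, _ = generate_peaks(cfg, None)
        shared = {p.name for i, p in enumerate(peaks) if i % 3 == 0}
        segs = generate_states(cfg, peaks, shared)
        from peakcalibre.comparative import assign_states
        states, n_fallback = assign_states(peaks, segs)
        assert n_fallback == 0
        for p in peaks:
            if p.name in shared:
                assert states[p.name] in ("TssAFlnk", "Enh")

    def test_segments_tile_without_overlap(self):
        peaks, _ = generate_peaks(SMALL, None)
        shared = {p.name for i, p in enumerate(peaks) if i % 4 == 0}
        segs = generate_states(SMALL, peaks, shared)
        by_chrom = {}
        for seg in segs:
            by_chrom.setdefault(seg.interval.chrom, []).append(seg.interval)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: iv.start)
            assert ivs[0].start == 0
            assert ivs[-1].end == SMALL.chrom_length
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start   # contiguous, non-overlapping tiling

    def test_distribution_separates_shared_from_specific(self):
        cfg = SyntheticConfig(seed=14, n_peaks=600)
        peaks, _ = generate_peaks(cfg, None)
        shared = {p.name for i, p in enumerate(peaks) if i % 3 == 0}
        segs = generate_states(cfg, peaks, shared)
        from peakcalibre.comparative import assign_states, state_distribution
        states, _ = assign_states(peaks, segs)
        dist = state_distribution(states, {
            "shared": sorted(shared),
            "specific": sorted({p.name for p in peaks} - shared),
        })
        active_shared = dist["shared"]["TssAFlnk"] + dist["shared"]["Enh"]
        assert active_shared > 0.75          # bias 0.9, minus window truncation
        assert dist["specific"]["Quies"] > 0.75


class TestWorkspace:
    def test_files_reparse_through_io(self, small_workspace):
        ws = small_workspace
        peaks = io.parse_narrowpeak(ws.peaks)
        assert len(peaks) == 300 + SyntheticConfig().n_decoys
        io.parse_narrowpeak(ws.companion_b)
        io.parse_bed3(ws.blacklist)
        io.parse_states_bed(ws.states)
        genes = io.parse_gene_table(ws.genes)
        assert len(genes) == SyntheticConfig().n_genes
        up, down = io.parse_gene_list(ws.modulated_genes)
        assert up and down
        seqs = io.parse_fasta(ws.peak_sequences)
        assert set(seqs) == {p.name for p in peaks}
        assert len(io.parse_pwm_text(ws.pwms)) == 4

    def test_truth_table_aligns_with_peaks(self, small_workspace):
        truth = pd.read_csv(small_workspace.truth_peaks, sep="\t")
        peaks = io.parse_narrowpeak(small_workspace.peaks)
        assert list(truth["name"]) == [p.name for p in peaks]
        assert truth.loc[~truth.is_decoy, "fold_enrichment"].le(50).all()

    def test_workspace_fully_deterministic(self, tmp_path):
        cfg = SyntheticConfig(seed=21, n_peaks=120)
        ws1 = generate_workspace(cfg, tmp_path / "a")
        ws2 = generate_workspace(cfg, tmp_path / "b")
        for name in ("peaks", "companion_b", "companion_c", "blacklist",
                     "states", "modulated_genes", "genes", "peak_sequences",
                     "genome_fasta", "truth_peaks", "truth_shared", "pwms"):
            f1, f2 = getattr(ws1, name), getattr(ws2, name)
            assert f1.read_bytes() == f2.read_bytes(), name
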