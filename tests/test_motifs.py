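"""PWM scoring/scanning, motif classification and group statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from peakcalibre.core import GenomicInterval, Peak
from peakcalibre.motifs import (
    MotifHit,
    PeakMotifClass,
    builtin_pwms,
    class_fraction_curve,
    classify_peaks,
    compound_motif_report,
    group_fe_test,
    log_odds_score,
    pwm_from_consensus,
    pwm_from_counts,
    reverse_complement,
    scan_sequence,
    scan_peak_sequences,
    shuffle_enrichment,
    summit_centering_profile,
)


@pytest.fixture(scope="module")
def ets():
    return pwm_from_consensus("ETS", "ETS", "ACCGGAAGTG")


@pytest.fixture(scope="module")
def runx():
    return pwm_from_consensus("RUNX", "RUNX", "ATCTGTGGTT")


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPwmConstruction:
    def test_rows_sum_to_one_and_positive(self):
        for pwm in builtin_pwms():
            np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
            assert (pwm.probs > 0).all()
            assert len(pwm) >= 4

    def test_consensus_recovered(self, ets):
        assert ets.consensus == "ACCGGAAGTG"

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pwm_from_consensus("x", "ETS", "ACG")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            pwm_from_consensus("x", "WEIRD", "ACGTACGT")

    def test_counts_normalised_per_column(self):
        pwm = pwm_from_counts("m", "OTHER", [[8, 0, 0, 2], [0, 8, 0, 2],
                                             [2, 0, 8, 2], [0, 2, 2, 4]])
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert pwm.consensus == "ACGT"


class TestLogOddsScore:
    def test_uniform_pwm_scores_zero_everywhere(self):
        uniform = pwm_from_counts("u", "OTHER", [[1] * 6] * 4, pseudocount=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert log_odds_score(random_seq(rng, 6), uniform) == pytest.approx(0.0)

    def test_consensus_achieves_the_maximum(self, ets):
        assert log_odds_score(ets.consensus, ets) == pytest.approx(ets.max_score)
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert log_odds_score(random_seq(rng, len(ets)), ets) \
                <= ets.max_score + 1e-12

    def test_n_contributes_zero(self, ets):
        with_n = "N" + ets.consensus[1:]
        without = ets.consensus
        diff = log_odds_score(without, ets) - log_odds_score(with_n, ets)
        assert diff == pytest.approx(math.log(ets.probs[0, 0] / 0.25))

    def test_matches_per_position_recomputation(self, ets):
        rng = np.random.default_rng(2)
        lo = np.log(ets.probs / 0.25)
        for _ in range(100):
            window = random_seq(rng, len(ets))
            expected = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(window))
            assert log_odds_score(window, ets) == pytest.approx(expected)

    def test_wrong_length_rejected(self, ets):
        with pytest.raises(ValueError, match="length"):
            log_odds_score("ACGT", ets)


class TestScanSequence:
    def test_planted_consensus_found_at_offset(self, ets):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 10) + ets.consensus + random_seq(rng, 30)
        hits = scan_sequence(seq, ets)
        assert any(h.offset == 10 and h.strand == "+" for h in hits)

    def test_reverse_complement_found_on_minus(self, ets):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 15) + reverse_complement(ets.consensus) \
            + random_seq(rng, 25)
        hits = scan_sequence(seq, ets)
        assert any(h.offset == 15 and h.strand == "-" for h in hits)

    def test_matches_exhaustive_sliding_window_oracle(self, ets, runx):
        rng = np.random.default_rng(5)
        for pwm in (ets, runx):
            cutoff = 0.5 * pwm.max_score   # low cutoff so hits actually occur
            for _ in range(100):
                seq = random_seq(rng, 80)
                expected = set()
                for off in range(len(seq) - len(pwm) + 1):
                    window = seq[off:off + len(pwm)]
                    if log_odds_score(window, pwm) >= cutoff - 1e-12:
                        expected.add((off, "+"))
                    if log_odds_score(reverse_complement(window), pwm) \
                            >= cutoff - 1e-12:
                        expected.add((off, "-"))
                got = {(h.offset, h.strand)
                       for h in scan_sequence(seq, pwm, frac_threshold=0.5)}
                assert got == expected

    def test_strand_symmetry(self, ets):
        rng = np.random.default_rng(6)
        for _ in range(50):
            seq = random_seq(rng, 60)
            fwd = {(h.offset, h.strand) for h in
                   scan_sequence(seq, ets, frac_threshold=0.5)}
            rc = {(h.offset, h.strand) for h in
                  scan_sequence(reverse_complement(seq), ets, frac_threshold=0.5)}
            L = len(ets)
            mirrored = {(len(seq) - L - off, "+-"[strand == "+"])
                        for off, strand in fwd}
            assert rc == mirrored

    def test_sequence_shorter_than_motif(self, ets):
        assert scan_sequence("ACG", ets) == []


class TestClassifyPeaks:
    def _classes(self, seqs):
        pwms = builtin_pwms()
        hits = scan_peak_sequences(seqs, pwms)
        return classify_peaks(seqs, hits, pwms)

    def test_four_way_assignment(self):
        rng = np.random.default_rng(7)
        pwms = {p.family: p.consensus for p in builtin_pwms()}
        pad = lambda: random_seq(rng, 40)
        seqs = {
            "ets": pad() + pwms["ETS"] + pad(),
            "runx": pad() + pwms["RUNX"] + pad(),
            "both": pad() + pwms["ETS"] + pad() + pwms["RUNX"] + pad(),
            "none": pad() + pad(),
            "compound": pad() + pwms["ETS_IRF_COMPOUND"] + pad(),
        }
        classes = self._classes(seqs)
        assert classes["ets"].motif_class is PeakMotifClass.ETS_ONLY
        assert classes["runx"].motif_class is PeakMotifClass.RUNX_ONLY
        assert classes["both"].motif_class is PeakMotifClass.ETS_RUNX
        assert classes["none"].motif_class is PeakMotifClass.NEITHER
        assert classes["compound"].motif_class is PeakMotifClass.NEITHER
        assert classes["compound"].has_ets_irf_compound

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(8)
        seqs = {f"p{i}": random_seq(rng, 120) for i in range(100)}
        classes = self._classes(seqs)
        assert set(classes) == set(seqs)


class TestSummitProfile:
    def _peak(self, name, width=400, summit=200):
        return Peak(GenomicInterval("chr1", 0, width), name, 5.0, 9.0, 7.0, summit)

    def test_hit_centered_at_summit_lands_in_first_positive_bin(self, ets):
        peak = self._peak("p")
        hit = MotifHit("p", "ETS", 200 - len(ets) // 2, "+", 5.0)
        profile = summit_centering_profile([hit], {"p": peak}, [ets])
        by_bin = {(s, e): c for s, e, c in profile["ETS"]}
        assert by_bin[(0, 50)] == 1

    def test_empty_hit_list(self, ets):
        assert summit_centering_profile([], {}, [ets]) == {}

    def test_gaussian_planted_offsets_peak_at_zero(self, ets):
        rng = np.random.default_rng(9)
        peak = self._peak("p", width=1_200, summit=600)
        hits = []
        for _ in range(2_000):
            center = 600 + int(rng.normal(0, 40))
            hits.append(MotifHit("p", "ETS", center - len(ets) // 2, "+", 5.0))
        profile = summit_centering_profile(hits, {"p": peak}, [ets])
        top = max(profile["ETS"], key=lambda row: row[2])
        assert top[0] <= 0 <= top[1]

    def test_in_window_count_conserved(self, ets):
        rng = np.random.default_rng(10)
        peak = self._peak("p", width=2_000, summit=1_000)
        hits = [MotifHit("p", "ETS", int(rng.integers(0, 1_990)), "+", 5.0)
                for _ in range(300)]
        profile = summit_centering_profile(hits, {"p": peak}, [ets])
        expected = sum(
            1 for h in hits
            if -500 <= (h.offset + len(ets) // 2 - 1_000) < 500)
        assert sum(c for _, _, c in profile["ETS"]) == expected


class TestClassFractionCurve:
    def _peaks(self, fes):
        return [Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 200),
                     f"p{i}", fe, 9.0, 7.0, 100) for i, fe in enumerate(fes)]

    def test_single_class_fraction_is_one(self):
        peaks = self._peaks([3.0, 5.0, 8.0])
        classes = {p.name: classify_stub(PeakMotifClass.ETS_ONLY) for p in peaks}
        curve = class_fraction_curve(peaks, classes, [2.0, 4.0, 6.0])
        assert all(r["ETS_ONLY"] == 1.0 for r in curve)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        peaks = self._peaks(rng.uniform(1, 12, 500))
        choices = list(PeakMotifClass)
        classes = {p.name: classify_stub(choices[rng.integers(4)]) for p in peaks}
        for row in class_fraction_curve(peaks, classes, [2.0, 5.0, 8.0]):
            total = sum(row[c.value] for c in PeakMotifClass)
            assert total == pytest.approx(1.0)

    def test_empty_selection_reports_nan(self):
        peaks = self._peaks([3.0])
        classes = {"p0": classify_stub(PeakMotifClass.NEITHER)}
        (row,) = class_fraction_curve(peaks, classes, [99.0])
        assert math.isnan(row["NEITHER"])

    def test_equal_fe_distributions_track_class_priors(self):
        rng = np.random.default_rng(12)
        n = 5_000
        fes = rng.lognormal(1.5, 0.5, n)
        idx = rng.choice(2, size=n, p=[0.7, 0.3])
        labels = [(PeakMotifClass.ETS_ONLY, PeakMotifClass.NEITHER)[i] for i in idx]
        peaks = self._peaks(fes)
        classes = {p.name: classify_stub(labels[i]) for i, p in enumerate(peaks)}
        for row in class_fraction_curve(peaks, classes, [2.0, 4.0, 6.0]):
            assert row["ETS_ONLY"] == pytest.approx(0.7, abs=0.05)


def classify_stub(cls, compound=False):
    from peakcalibre.motifs import PeakClassification
    return PeakClassification(cls, compound)


class TestGroupFeTest:
    def test_identical_groups_give_t_zero_p_one(self):
        r = group_fe_test([1, 2, 3], [1, 2, 3])
        assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # {1,2,3,4} vs {2,3,4,5}: pooled s^2 = 5/3, t = -1/sqrt(5/6)
        r = group_fe_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.t_statistic == pytest.approx(-math.sqrt(6 / 5), rel=1e-12)
        assert r.df == 6
        expected_p = 2 * stats.t.sf(math.sqrt(6 / 5), 6)
        assert r.p_value == pytest.approx(expected_p, rel=1e-12)

    def test_matches_scipy_pooled_and_welch(self):
        rng = np.random.default_rng(13)
        a = rng.normal(5, 2, 40)
        b = rng.normal(6, 3, 25)
        r = group_fe_test(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert r.t_statistic == pytest.approx(t) and r.p_value == pytest.approx(p)
        rw = group_fe_test(a, b, welch=True)
        tw, pw = stats.ttest_ind(a, b, equal_var=False)
        assert rw.t_statistic == pytest.approx(tw) and rw.p_value == pytest.approx(pw)

    def test_zero_variance_convention(self):
        r = group_fe_test([2, 2, 2], [2, 2])
        assert r.t_statistic == 0.0 and r.p_value == 1.0
        r2 = group_fe_test([3, 3, 3], [2, 2])
        assert r2.p_value == 0.0

    def test_whisker_summaries(self):
        values = list(range(1, 101))
        r = group_fe_test(values, values)
        p5, median, p95 = r.summary_a
        assert p5 == pytest.approx(np.percentile(values, 5))
        assert median == pytest.approx(50.5)
        assert p95 == pytest.approx(np.percentile(values, 95))

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_fe_test([1], [1, 2])


class TestCompoundReport:
    def test_no_hits_gives_zero_counts(self):
        classes = {"p1": classify_stub(PeakMotifClass.NEITHER)}
        report = compound_motif_report(classes, [], builtin_pwms(), {"p1": True})
        assert report["n_neither"] == 1
        assert report["n_neither_with_compound"] == 0

    def test_planted_compound_counts_recovered(self):
        rng = np.random.default_rng(14)
        pwms = builtin_pwms()
        compound = next(p for p in pwms if p.family == "ETS_IRF_COMPOUND")
        seqs, corr = {}, {}
        planted = 0
        for i in range(60):
            name = f"p{i}"
            has = i % 2 == 0
            planted += has
            body = random_seq(rng, 80)
            if has:
                body = body[:30] + compound.consensus + body[30 + len(compound):]
            seqs[name] = body
            corr[name] = i % 3 == 0
        hits = scan_peak_sequences(seqs, pwms)
        classes = classify_peaks(seqs, hits, pwms)
        report = compound_motif_report(classes, hits, pwms, corr)
        neither_with = {n for n, c in classes.items()
                        if c.motif_class is PeakMotifClass.NEITHER
                        and c.has_ets_irf_compound}
        assert report["n_neither_with_compound"] == len(neither_with)
        # brute-force recount: planted peaks that stayed NEITHER
        expected = sum(
            1 for i in range(60)
            if i % 2 == 0
            and classes[f"p{i}"].motif_class is PeakMotifClass.NEITHER)
        assert report["n_neither_with_compound"] == expected
        assert expected >= planted - 3   # at most a few random ETS/RUNX hits


def test_shuffle_enrichment_detects_planted_motif(ets):
    rng = np.random.default_rng(15)
    seqs = {f"p{i}": random_seq(rng, 30) + ets.consensus + random_seq(rng, 30)
            for i in range(30)}
    result = shuffle_enrichment(seqs, ets, n_shuffles=20, seed=1)
    assert result["observed_fraction"] == 1.0
    assert result["enrichment"] > 3
    assert result["empirical_p"] < 0.1
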