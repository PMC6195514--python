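"""PWM log-odds scanning and motif-class analysis of peak sequences.

Scanning uses a log-odds score against a uniform 0.25 background; a
window is a hit when its score reaches a configurable fraction (default
0.8) of the motif's maximum achievable score.  Peaks are then classified
four ways by the presence of ETS- and RUNX-family hits, with an
ETS-IRF compound motif tracked separately (it is reported for peaks
lacking both ETS and RUNX).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import Peak

MOTIF_FAMILIES = ("ETS", "RUNX", "IRF", "ETS_IRF_COMPOUND", "OTHER")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PeakMotifClass(str, Enum):
    ETS_ONLY = "ETS_ONLY"
    RUNX_ONLY = "RUNX_ONLY"
    ETS_RUNX = "ETS_RUNX"
    NEITHER = "NEITHER"


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over A, C, G, T (columns) with a family tag.

    ``counts`` preserves the parsed matrix so writing and re-reading the
    motif reproduces identical probabilities; ``probs`` carries the
    pseudocounted per-position probabilities used for scoring.
    """

    id: str
    family: str
    probs: np.ndarray        # (L, 4)
    counts: np.ndarray       # (L, 4), as parsed / constructed

    def __post_init__(self) -> None:
        if self.family not in MOTIF_FAMILIES:
            raise ValueError(f"unknown motif family {self.family!r}")
        if self.probs.shape[0] < 4:
            raise ValueError(f"motif {self.id}: length must be >= 4")
        if self.probs.shape[1] != 4:
            raise ValueError(f"motif {self.id}: need 4 base columns")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"motif {self.id}: rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError(f"motif {self.id}: probabilities must be > 0")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def pwm_from_counts(
    motif_id: str,
    family: str,
    counts: Sequence[Sequence[float]],
    pseudocount: float = 0.01,
) -> PWM:
    """Build a PWM from per-base count rows (A, C, G, T order, one row per
    base as in JASPAR text).  Counts are column-normalised, then the
    pseudocount is added and renormalised so every probability is > 0."""
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != 4:
        raise ValueError(f"motif {motif_id}: expected 4 count rows")
    mat = mat.T  # -> (L, 4)
    if (mat < 0).any():
        raise ValueError(f"motif {motif_id}: negative count")
    colsum = mat.sum(axis=1, keepdims=True)
    if (colsum == 0).any():
        raise ValueError(f"motif {motif_id}: empty count column")
    probs = mat / colsum + pseudocount
    probs /= probs.sum(axis=1, keepdims=True)
    return PWM(id=motif_id, family=family, probs=probs, counts=mat)


def pwm_from_consensus(
    motif_id: str,
    family: str,
    consensus: str,
    major_weight: float = 0.91,
    pseudocount: float = 0.01,
) -> PWM:
    """A sharply peaked PWM from a consensus string; ``N`` positions are
    uniform.  Used for the bundled example motif library."""
    counts = np.full((4, len(consensus)), (1 - major_weight) / 3)
    for j, base in enumerate(consensus.upper()):
        if base == "N":
            counts[:, j] = 0.25
        else:
            counts[_BASE_INDEX[base], j] = major_weight
    return pwm_from_counts(motif_id, family, counts, pseudocount=pseudocount)


def builtin_pwms() -> list[PWM]:
    """The bundled example motif library.

    These are sharp consensus models for the motif families relevant to
    ETV6 ChIP-seq in t(12;21) cells: an ETS motif (GGAA core, the
    ETV6/ETS-family site), a RUNX motif (TGTGGT core, the Runt-domain
    site bound via the ETV6-RUNX1 fusion), an ISRE-style IRF motif, and
    an ETS-IRF compound element (EICE-like GGAA..TGAAA arrangement).
    """
    return [
        pwm_from_consensus("ETS_GGAA", "ETS", "ACCGGAAGTG"),
        pwm_from_consensus("RUNX_TGTGGT", "RUNX", "ATCTGTGGTT"),
        pwm_from_consensus("IRF_ISRE", "IRF", "GCTTTCACTTTC"),
        pwm_from_consensus("ETS_IRF_EICE", "ETS_IRF_COMPOUND", "GGAAGTGAAAC"),
    ]


@dataclass(frozen=True)
class MotifHit:
    peak_name: str
    pwm_id: str
    offset: int          # hit start within the peak sequence
    strand: str
    score: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def log_odds_score(window: str, pwm: PWM) -> float:
    """Sum of per-position log(p_base / 0.25); an ``N`` contributes 0."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != motif length {len(pwm)}")
    lo = pwm.log_odds
    score = 0.0
    for i, base in enumerate(window.upper()):
        if base == "N":
            continue
        score += lo[i, _BASE_INDEX[base]]
    return score


def _encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; N (or any non-ACGT) -> 4."""
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def scan_sequence(
    seq: str,
    pwm: PWM,
    peak_name: str = "",
    frac_threshold: float = 0.8,
) -> list[MotifHit]:
    """All windows (both strands) scoring >= ``frac_threshold * max_score``.

    Minus-strand windows score the reverse complement of the window; the
    reported offset is the window's start on the given (plus) sequence.
    """
    seq = seq.upper()
    L = len(pwm)
    if len(seq) < L:
        return []
    cutoff = frac_threshold * pwm.max_score
    lo = np.vstack([pwm.log_odds.T, np.zeros(len(pwm))]).T  # row 4 = N -> 0
    codes = _encode(seq)
    n_win = len(seq) - L + 1
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    # minus strand: revcomp(window)[i] = complement(window[L-1-i])
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    for i in range(L):
        fwd += lo[i, codes[i:i + n_win]]
        rev += lo[i, comp[codes[L - 1 - i:L - 1 - i + n_win]]]
    hits = [
        MotifHit(peak_name, pwm.id, int(off), "+", float(fwd[off]))
        for off in np.nonzero(fwd >= cutoff - 1e-12)[0]
    ] + [
        MotifHit(peak_name, pwm.id, int(off), "-", float(rev[off]))
        for off in np.nonzero(rev >= cutoff - 1e-12)[0]
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_peak_sequences(
    seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    frac_threshold: float = 0.8,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for name in seqs:
        for pwm in pwms:
            hits.extend(scan_sequence(seqs[name], pwm, peak_name=name,
                                      frac_threshold=frac_threshold))
    return hits


@dataclass(frozen=True)
class PeakClassification:
    motif_class: PeakMotifClass
    has_ets_irf_compound: bool


def classify_peaks(
    peak_names: Iterable[str],
    hits: Iterable[MotifHit],
    pwms: Sequence[PWM],
) -> dict[str, PeakClassification]:
    """Four-way class per peak from the presence of ETS/RUNX-family hits,
    plus the ETS-IRF compound flag (meaningful mainly for NEITHER peaks)."""
    family_of = {p.id: p.family for p in pwms}
    fams: dict[str, set[str]] = {}
    for hit in hits:
        fams.setdefault(hit.peak_name, set()).add(family_of[hit.pwm_id])
    out: dict[str, PeakClassification] = {}
    for name in peak_names:
        present = fams.get(name, set())
        has_ets = "ETS" in present
        has_runx = "RUNX" in present
        if has_ets and has_runx:
            cls = PeakMotifClass.ETS_RUNX
        elif has_ets:
            cls = PeakMotifClass.ETS_ONLY
        elif has_runx:
            cls = PeakMotifClass.RUNX_ONLY
        else:
            cls = PeakMotifClass.NEITHER
        out[name] = PeakClassification(cls, "ETS_IRF_COMPOUND" in present)
    return out


def summit_centering_profile(
    hits: Iterable[MotifHit],
    peaks: Mapping[str, Peak],
    pwms: Sequence[PWM],
    window: int = 500,
    bin_size: int = 50,
) -> dict[str, list[tuple[int, int, int]]]:
    """Per-family histogram of (hit center - peak summit) offsets.

    Returns family -> (bin_start, bin_end, count) rows over
    ``[-window, +window)``; hits outside the window are dropped.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin size")
    length_of = {p.id: len(p) for p in pwms}
    family_of = {p.id: p.family for p in pwms}
    n_side = window // bin_size
    counts: dict[str, list[int]] = {}
    for hit in hits:
        peak = peaks[hit.peak_name]
        summit_in_seq = (peak.summit_offset if peak.summit_offset is not None
                         else len(peak.interval) // 2)
        center = hit.offset + length_of[hit.pwm_id] // 2
        d = center - summit_in_seq
        if -window <= d < window:
            fam = family_of[hit.pwm_id]
            counts.setdefault(fam, [0] * (2 * n_side))[d // bin_size + n_side] += 1
    return {
        fam: [((i - n_side) * bin_size, (i - n_side + 1) * bin_size, c)
              for i, c in enumerate(bins)]
        for fam, bins in counts.items()
    }


def class_fraction_curve(
    peaks: Sequence[Peak],
    classes: Mapping[str, PeakClassification],
    grid: Sequence[float],
) -> list[dict[str, float]]:
    """Per-class fraction of peaks with FE >= t, for each grid threshold.

    Fractions sum to 1 across the four classes at each threshold; a
    threshold retaining no peaks reports NaN fractions.
    """
    rows: list[dict[str, float]] = []
    for t in grid:
        selected = [p for p in peaks if p.fold_enrichment >= t]
        row: dict[str, float] = {"threshold": t, "n_peaks": len(selected)}
        if not selected:
            for cls in PeakMotifClass:
                row[cls.value] = float("nan")
        else:
            for cls in PeakMotifClass:
                n = sum(1 for p in selected
                        if classes[p.name].motif_class is cls)
                row[cls.value] = n / len(selected)
        rows.append(row)
    return rows


@dataclass(frozen=True)
class GroupTestResult:
    t_statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    summary_a: tuple[float, float, float]   # 5th percentile, median, 95th
    summary_b: tuple[float, float, float]


def _whisker_summary(values: np.ndarray) -> tuple[float, float, float]:
    return (float(np.percentile(values, 5)), float(np.median(values)),
            float(np.percentile(values, 95)))


def group_fe_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> GroupTestResult:
    """Two-sample Student's t test on fold enrichments (pooled variance by
    default; Welch behind a flag), with 5-95 percentile whisker summaries.

    When both groups have zero variance, p = 1 if the means are equal
    (t = 0) and p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / len(a) + vb / len(b)
        df = (se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1)
                          + (vb / len(b)) ** 2 / (len(b) - 1))
              if se2 > 0 else float(len(a) + len(b) - 2))
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se2 = sp2 * (1 / len(a) + 1 / len(b))
        df = float(len(a) + len(b) - 2)
    if se2 == 0:
        t = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t = (ma - mb) / math.sqrt(se2)
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupTestResult(t, p, df, float(ma), float(mb),
                           _whisker_summary(a), _whisker_summary(b))


def compound_motif_report(
    classes: Mapping[str, PeakClassification],
    hits: Iterable[MotifHit],
    pwms: Sequence[PWM],
    expression_correlated: Mapping[str, bool],
) -> dict[str, int]:
    """Counts of NEITHER-class peaks carrying IRF or ETS-IRF compound hits,
    split by expression-correlated status."""
    family_of = {p.id: p.family for p in pwms}
    irf_peaks: set[str] = set()
    compound_peaks: set[str] = set()
    for hit in hits:
        fam = family_of[hit.pwm_id]
        if fam == "IRF":
            irf_peaks.add(hit.peak_name)
        elif fam == "ETS_IRF_COMPOUND":
            compound_peaks.add(hit.peak_name)
    neither = {n for n, c in classes.items()
               if c.motif_class is PeakMotifClass.NEITHER}
    corr = {n for n in neither if expression_correlated.get(n, False)}
    return {
        "n_neither": len(neither),
        "n_neither_expression_correlated": len(corr),
        "n_neither_with_irf": len(neither & irf_peaks),
        "n_neither_with_compound": len(neither & compound_peaks),
        "n_corr_neither_with_irf": len(corr & irf_peaks),
        "n_corr_neither_with_compound": len(corr & compound_peaks),
    }


def shuffle_enrichment(
    seqs: Mapping[str, str],
    pwm: PWM,
    n_shuffles: int = 100,
    frac_threshold: float = 0.8,
    seed: int = 0,
) -> dict[str, float]:
    """Hit-frequency enrichment versus mononucleotide-shuffled sequences.

    Reports the observed fraction of sequences with >= 1 hit, the mean
    shuffled fraction, their ratio, and an empirical one-sided p-value
    (the fraction of shuffles with at least the observed hit frequency,
    with the +1 continuity correction).
    """
    rng = np.random.default_rng(seed)
    names = list(seqs)
    obs = sum(
        1 for n in names
        if scan_sequence(seqs[n], pwm, frac_threshold=frac_threshold)
    )
    null_counts = []
    for _ in range(n_shuffles):
        count = 0
        for n in names:
            arr = np.frombuffer(seqs[n].encode(), dtype=np.uint8).copy()
            rng.shuffle(arr)
            if scan_sequence(arr.tobytes().decode(), pwm,
                             frac_threshold=frac_threshold):
                count += 1
        null_counts.append(count)
    null = np.array(null_counts, dtype=float)
    mean_null = float(null.mean())
    p = (1.0 + float((null >= obs).sum())) / (n_shuffles + 1.0)
    return {
        "observed_fraction": obs / len(names) if names else float("nan"),
        "shuffled_fraction": mean_null / len(names) if names else float("nan"),
        "enrichment": (obs / mean_null) if mean_null > 0 else float("inf"),
        "empirical_p": p,
    }
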