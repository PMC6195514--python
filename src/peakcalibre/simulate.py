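"""Seeded synthetic-data generator with planted ground truth.

Emulates every input the pipeline consumes: a random genome, gene
models, peak calls whose fold-enrichment distribution differs by a
planted motif class, consensus motif instances written into the genome
around peak summits, a logistic-style coupling between peak strength and
gene modulation, two companion peak sets with planted overlap fractions,
a chromatin-state segmentation biased by shared/specific status, a
blacklist, and deliberate QC-violating decoy peaks.

Everything is a pure function of the configuration (including its seed):
one global seed fans out to fixed per-stage child streams, so any stage
can be regenerated independently and all outputs are byte-identical
across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import ChromatinStateSegment, GeneModel, GenomicInterval, Peak
from .motifs import builtin_pwms, reverse_complement
from .peaks import associate_closest_tss

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed per-stage stream ids (seed fan-out offsets).
_STAGES = {
    "genome": 1, "genes": 2, "peaks": 3, "blacklist": 4, "decoys": 5,
    "expression": 6, "companions": 7, "states": 8,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the package's study conditions."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_genes: int = 3_000
    n_peaks: int = 2_000
    #: priors over (ETS_ONLY, RUNX_ONLY, ETS_RUNX, NEITHER)
    class_priors: tuple[float, float, float, float] = (0.30, 0.17, 0.15, 0.38)
    #: per-class log-FE mean; ETS-containing classes are stronger
    fe_log_mean: dict[str, float] = field(default_factory=lambda: {
        "ETS_ONLY": math.log(6.0), "ETS_RUNX": math.log(6.0),
        "RUNX_ONLY": math.log(4.0), "NEITHER": math.log(4.0),
    })
    fe_log_sigma: float = 0.5
    fe_cap: float = 50.0
    # expression coupling: P(modulated) = boosted_rate if the gene's best
    # associated peak has FE >= coupling_t0, else base_rate
    coupling_t0: float = 4.5
    base_rate: float = 0.01
    boosted_rate: float = 0.5
    up_down_counts: tuple[int, int] = (59, 88)   # up:down split ratio
    # companion peak sets (planted cross-cell-line overlap)
    p_ab: float = 0.19
    p_ac: float = 0.048
    p_abc: float = 0.035
    companion_sizes: tuple[int, int] = (3_000, 3_000)
    companion_jitter: int = 50
    # chromatin states
    state_bias_shared: float = 0.9     # P(shared peak window -> TssAFlnk/Enh)
    state_bias_specific: float = 0.9   # P(specific peak stays Quies)
    state_pad: int = 200
    # motif planting
    motif_offset_sigma: float = 40.0
    motif_mutation_rate: float = 0.0
    compound_in_neither: float = 0.25
    # peak geometry and decoys
    peak_width_min: int = 200
    peak_width_max: int = 500
    n_blacklist: int = 10
    blacklist_len: int = 2_000
    n_decoys: int = 20

    def __post_init__(self) -> None:
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if not (0 < self.base_rate < 1 and 0 < self.boosted_rate < 1):
            raise ValueError("rates must lie in (0, 1)")
        if self.boosted_rate <= self.base_rate:
            raise ValueError("boosted_rate must exceed base_rate")
        for p in (self.p_ab, self.p_ac, self.p_abc):
            if not 0 <= p <= 1:
                raise ValueError("overlap fractions must lie in [0, 1]")
        if self.p_abc > min(self.p_ab, self.p_ac):
            raise ValueError("p_abc cannot exceed min(p_ab, p_ac)")
        if self.chrom_length < 10_000:
            raise ValueError("chromosomes must be >= 10 kb")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, _STAGES[stage]))
        )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


_CLASS_ORDER = ("ETS_ONLY", "RUNX_ONLY", "ETS_RUNX", "NEITHER")


# ---------------------------------------------------------------------------
# genome and genes

def generate_genome(config: SyntheticConfig) -> dict[str, bytearray]:
    """Uniform-random A/C/G/T sequence per chromosome (mutable, so peak
    generation can write motif instances into it)."""
    rng = config.rng("genome")
    return {
        chrom: bytearray(
            _BASES[rng.integers(0, 4, config.chrom_length, dtype=np.uint8)].tobytes()
        )
        for chrom in config.chrom_names
    }


def generate_genes(config: SyntheticConfig) -> list[GeneModel]:
    """Genes with uniform TSS positions, random strands and 1-5 exons."""
    rng = config.rng("genes")
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(1_000, 10_000))
        start = int(rng.integers(0, config.chrom_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval(chrom, start, start + length)
        n_exons = int(rng.integers(1, 6))
        bounds = np.sort(rng.choice(
            np.arange(start + 1, start + length), size=2 * n_exons, replace=False,
        ))
        exons = tuple(
            GenomicInterval(chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]))
            for j in range(n_exons)
            if bounds[2 * j] < bounds[2 * j + 1]
        )
        genes.append(GeneModel(f"g{i + 1:06d}", chrom, strand, span, exons))
    return genes


# ---------------------------------------------------------------------------
# peaks

@dataclass
class _Placement:
    """Occupied intervals per chromosome, for non-overlapping placement."""

    occupied: dict[str, list[tuple[int, int]]]

    @classmethod
    def empty(cls, config: SyntheticConfig) -> "_Placement":
        return cls({c: [] for c in config.chrom_names})

    def try_place(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.occupied[chrom]:
            if start < e and s < end:
                return False
        self.occupied[chrom].append((start, end))
        return True


def _place_peak(rng, config, placement, width) -> tuple[str, int] | None:
    for _ in range(200):
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - width))
        if placement.try_place(chrom, start, start + width):
            return chrom, start
    return None


def _signal_columns(rng, fe: float) -> tuple[float, float]:
    """-log10 p/q loosely increasing with fold enrichment (always passing
    the default q <= 0.1 filter, as MACS output post-thresholding would)."""
    nlq = 1.0 + fe / 2.0 + float(rng.exponential(1.0))
    return nlq + 2.0, nlq


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def generate_peaks(
    config: SyntheticConfig,
    genome: dict[str, bytearray] | None,
) -> tuple[list[Peak], pd.DataFrame]:
    """Primary peak set with planted classes, FE distributions and motifs.

    Each peak draws a latent motif class from the priors and a fold
    enrichment from that class's lognormal; consensus instances of the
    class's motifs (ETS and/or RUNX; optionally the ETS-IRF compound for
    NEITHER peaks) are written into ``genome`` at Gaussian offsets around
    the summit.  Pass ``genome=None`` to skip sequence planting (peak
    tables only — enough for calibration experiments).

    Returns (peaks, truth table).  The truth table records the planted
    class, planted motif offsets and the decoy flag for every peak,
    including the deliberate QC-violating decoys appended at the end.
    """
    rng = config.rng("peaks")
    pwms = {p.family: p for p in builtin_pwms()}
    placement = _Placement.empty(config)
    peaks: list[Peak] = []
    truth_rows: list[dict] = []

    priors = np.asarray(config.class_priors)
    classes = rng.choice(len(_CLASS_ORDER), size=config.n_peaks, p=priors)

    for i in range(config.n_peaks):
        cls = _CLASS_ORDER[classes[i]]
        width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        placed = _place_peak(rng, config, placement, width)
        if placed is None:
            raise RuntimeError("genome too crowded to place peaks")
        chrom, start = placed
        summit = width // 2 + int(rng.integers(-20, 21))
        summit = min(max(summit, 0), width - 1)
        fe = float(np.exp(rng.normal(config.fe_log_mean[cls], config.fe_log_sigma)))
        fe = min(fe, config.fe_cap)  # stay below the QC cap
        nlp, nlq = _signal_columns(rng, fe)
        name = f"peak_{i + 1:05d}"
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), name,
                          fe, nlp, nlq, summit))

        to_plant = {"ETS_ONLY": ["ETS"], "RUNX_ONLY": ["RUNX"],
                    "ETS_RUNX": ["ETS", "RUNX"], "NEITHER": []}[cls]
        compound = cls == "NEITHER" and rng.random() < config.compound_in_neither
        if compound:
            to_plant = ["ETS_IRF_COMPOUND"]
        offsets: list[int] = []
        used: list[tuple[int, int]] = []
        for family in to_plant:
            motif = pwms[family].consensus
            off = _motif_offset(rng, config, summit, width, len(motif), used)
            used.append((off, off + len(motif)))
            offsets.append(off)
            if genome is not None:
                instance = _mutate(rng, motif, config.motif_mutation_rate)
                if rng.random() < 0.5:
                    instance = reverse_complement(instance)
                genome[chrom][start + off:start + off + len(motif)] = \
                    instance.encode()
        truth_rows.append({
            "name": name, "chrom": chrom, "start": start, "end": start + width,
            "summit_offset": summit, "motif_class": cls,
            "fold_enrichment": fe, "has_compound": compound,
            "planted_families": ",".join(to_plant),
            "planted_offsets": ",".join(map(str, offsets)),
            "is_decoy": False,
        })

    truth = pd.DataFrame(truth_rows)
    return peaks, truth


def _motif_offset(rng, config, summit, width, motif_len, used) -> int:
    """Gaussian offset around the summit, clipped into the peak and
    resampled away from already-planted instances."""
    for _ in range(100):
        center = summit + rng.normal(0.0, config.motif_offset_sigma)
        off = int(round(center - motif_len / 2))
        off = min(max(off, 0), width - motif_len)
        if all(off + motif_len <= s or e <= off for s, e in used):
            return off
    # crowded peak: fall back to a deterministic shift past the last instance
    last_end = max(e for _, e in used)
    return min(last_end, width - motif_len)


def generate_blacklist(
    config: SyntheticConfig, peaks: list[Peak]
) -> list[GenomicInterval]:
    """Random blacklist intervals, rejection-sampled away from the primary
    peaks so that QC drops only the deliberate decoys."""
    rng = config.rng("blacklist")
    placement = _Placement.empty(config)
    for p in peaks:
        placement.occupied[p.chrom].append((p.interval.start, p.interval.end))
    out: list[GenomicInterval] = []
    while len(out) < config.n_blacklist:
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.blacklist_len))
        if placement.try_place(chrom, start, start + config.blacklist_len):
            out.append(GenomicInterval(chrom, start, start + config.blacklist_len))
    return out


def generate_decoys(
    config: SyntheticConfig,
    blacklist: list[GenomicInterval],
    existing: list[Peak],
) -> tuple[list[Peak], pd.DataFrame]:
    """QC-violating peaks: half above the FE cap, half inside blacklist
    regions, so the filter stage has real work on the default workspace."""
    rng = config.rng("decoys")
    placement = _Placement.empty(config)
    for p in existing:
        placement.occupied[p.chrom].append((p.interval.start, p.interval.end))
    decoys: list[Peak] = []
    rows: list[dict] = []
    for i in range(config.n_decoys):
        width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        in_blacklist = bool(i % 2) and blacklist
        if in_blacklist:
            bl = blacklist[int(rng.integers(len(blacklist)))]
            start = max(0, bl.start - width // 2)
            chrom = bl.chrom
            fe = float(np.exp(rng.normal(math.log(4.0), config.fe_log_sigma)))
            fe = min(fe, config.fe_cap)
        else:
            placed = _place_peak(rng, config, placement, width)
            if placed is None:
                continue
            chrom, start = placed
            fe = config.fe_cap + float(rng.uniform(5.0, 30.0))
        nlp, nlq = _signal_columns(rng, min(fe, 20.0))
        name = f"decoy_{i + 1:03d}"
        decoys.append(Peak(GenomicInterval(chrom, start, start + width), name,
                           fe, nlp, nlq, width // 2))
        rows.append({
            "name": name, "chrom": chrom, "start": start, "end": start + width,
            "summit_offset": width // 2, "motif_class": "NEITHER",
            "fold_enrichment": fe, "has_compound": False,
            "planted_families": "", "planted_offsets": "", "is_decoy": True,
        })
    return decoys, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression coupling

def generate_expression(
    config: SyntheticConfig,
    peaks: list[Peak],
    genes: list[GeneModel],
) -> tuple[set[str], set[str]]:
    """Up/down modulated gene sets under the planted coupling.

    A gene whose best (max-FE) associated peak reaches ``coupling_t0`` is
    modulated with probability ``boosted_rate``; every other gene with
    probability ``base_rate``.  Modulated genes split up/down at random
    in the configured ratio.
    """
    rng = config.rng("expression")
    associations, _ = associate_closest_tss(peaks, genes)
    fe_of = {p.name: p.fold_enrichment for p in peaks}
    best_fe: dict[str, float] = {}
    for name, assoc in associations.items():
        fe = fe_of[name]
        if fe > best_fe.get(assoc.gene_id, 0.0):
            best_fe[assoc.gene_id] = fe
    up: set[str] = set()
    down: set[str] = set()
    n_up, n_down = config.up_down_counts
    p_up = n_up / (n_up + n_down)
    for gene in genes:
        rate = (config.boosted_rate
                if best_fe.get(gene.gene_id, 0.0) >= config.coupling_t0
                else config.base_rate)
        if rng.random() < rate:
            (up if rng.random() < p_up else down).add(gene.gene_id)
    return up, down


# ---------------------------------------------------------------------------
# companion peak sets

def generate_companion_sets(
    config: SyntheticConfig,
    peaks: list[Peak],
) -> tuple[list[Peak], list[Peak], pd.DataFrame]:
    """Two companion peak sets with planted overlap fractions.

    Each primary peak is copied (jittered <= ``companion_jitter`` bp)
    into set B with probability ``p_ab``, into C with ``p_ac``, and into
    both with ``p_abc``; the sets are then padded to their target sizes
    with private peaks rejection-sampled away from the primary set (so
    the recovered overlap fractions match the planted ones).
    """
    rng = config.rng("companions")
    shared_rows: list[dict] = []
    set_b: list[Peak] = []
    set_c: list[Peak] = []
    for peak in peaks:
        u = rng.random()
        if u < config.p_abc:
            in_b = in_c = True
        elif u < config.p_ab:
            in_b, in_c = True, False
        elif u < config.p_ab + (config.p_ac - config.p_abc):
            in_b, in_c = False, True
        else:
            in_b = in_c = False
        for flag, dest, tag in ((in_b, set_b, "B"), (in_c, set_c, "C")):
            if not flag:
                continue
            shift = int(rng.integers(-config.companion_jitter,
                                     config.companion_jitter + 1))
            iv = peak.interval
            start = max(0, iv.start + shift)
            end = min(config.chrom_length, iv.end + shift)
            dest.append(Peak(
                GenomicInterval(iv.chrom, start, end),
                f"{tag}_{peak.name}", peak.fold_enrichment,
                peak.neglog10_p, peak.neglog10_q, None,
            ))
        shared_rows.append({"name": peak.name, "in_b": in_b, "in_c": in_c})

    forbidden = _Placement.empty(config)
    for p in peaks:
        forbidden.occupied[p.chrom].append((p.interval.start, p.interval.end))
    for dest, tag, target in ((set_b, "B", config.companion_sizes[0]),
                              (set_c, "C", config.companion_sizes[1])):
        i = 0
        while len(dest) < target:
            width = int(rng.integers(config.peak_width_min,
                                     config.peak_width_max + 1))
            placed = _place_peak(rng, config, forbidden, width)
            if placed is None:
                break
            chrom, start = placed
            fe = float(np.exp(rng.normal(math.log(4.0), config.fe_log_sigma)))
            nlp, nlq = _signal_columns(rng, fe)
            i += 1
            dest.append(Peak(GenomicInterval(chrom, start, start + width),
                             f"{tag}_private_{i:05d}", min(fe, config.fe_cap),
                             nlp, nlq, None))
    return set_b, set_c, pd.DataFrame(shared_rows)


# ---------------------------------------------------------------------------
# chromatin states

_SHARED_STATES = ("TssAFlnk", "Enh")
_SPECIFIC_ESCAPE_STATES = ("TssA", "TxWk", "Het")


def generate_states(
    config: SyntheticConfig,
    peaks: list[Peak],
    shared_names: set[str],
) -> list[ChromatinStateSegment]:
    """Quies-background segmentation with planted biases.

    Windows (peak +- ``state_pad``) around shared peaks are relabeled
    TssAFlnk or Enh with probability ``state_bias_shared``; specific
    peaks stay on the Quies background with probability
    ``state_bias_specific`` (otherwise a random non-Quies state).
    Segments are non-overlapping and tile each chromosome completely.
    """
    rng = config.rng("states")
    windows: dict[str, list[tuple[int, int, str]]] = {
        c: [] for c in config.chrom_names
    }
    for peak in peaks:
        if peak.name in shared_names:
            if rng.random() >= config.state_bias_shared:
                continue
            state = _SHARED_STATES[int(rng.integers(len(_SHARED_STATES)))]
        else:
            if rng.random() < config.state_bias_specific:
                continue
            state = _SPECIFIC_ESCAPE_STATES[
                int(rng.integers(len(_SPECIFIC_ESCAPE_STATES)))]
        iv = peak.interval
        start = max(0, iv.start - config.state_pad)
        end = min(config.chrom_length, iv.end + config.state_pad)
        windows[iv.chrom].append((start, end, state))

    segments: list[ChromatinStateSegment] = []
    for chrom in config.chrom_names:
        pos = 0
        for start, end, state in sorted(windows[chrom]):
            start = max(start, pos)       # truncate at the previous window
            if start >= end:
                continue
            if start > pos:
                segments.append(ChromatinStateSegment(
                    GenomicInterval(chrom, pos, start), "Quies"))
            segments.append(ChromatinStateSegment(
                GenomicInterval(chrom, start, end), state))
            pos = end
        if pos < config.chrom_length:
            segments.append(ChromatinStateSegment(
                GenomicInterval(chrom, pos, config.chrom_length), "Quies"))
    return segments


# ---------------------------------------------------------------------------
# assembly

def extract_peak_sequences(
    genome: dict[str, bytearray], peaks: list[Peak]
) -> dict[str, str]:
    return {
        p.name: bytes(genome[p.chrom][p.interval.start:p.interval.end]).decode()
        for p in peaks
    }


@dataclass(frozen=True)
class Workspace:
    """Paths of a fully materialized synthetic input directory."""

    root: Path
    genome_fasta: Path
    chrom_sizes: Path
    genes: Path
    peaks: Path
    companion_b: Path
    companion_c: Path
    blacklist: Path
    states: Path
    modulated_genes: Path
    peak_sequences: Path
    pwms: Path
    truth_peaks: Path
    truth_shared: Path


def generate_workspace(
    config: SyntheticConfig,
    outdir: str | Path,
    write_genome: bool = True,
) -> Workspace:
    """Materialize a complete synthetic workspace directory.

    All files re-parse through :mod:`peakcalibre.io`; the two ``truth_*``
    tables carry the planted ground truth for recovery tests and are not
    pipeline inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    genes = generate_genes(config)
    peaks, truth = generate_peaks(config, genome)
    blacklist = generate_blacklist(config, peaks)
    decoys, decoy_truth = generate_decoys(config, blacklist, peaks)
    up, down = generate_expression(config, peaks, genes)
    set_b, set_c, shared = generate_companion_sets(config, peaks)
    shared_b = set(shared.loc[shared["in_b"], "name"])
    states = generate_states(config, peaks, shared_b)

    ws = Workspace(
        root=outdir,
        genome_fasta=outdir / "genome.fa",
        chrom_sizes=outdir / "chrom_sizes.tsv",
        genes=outdir / "genes.tsv",
        peaks=outdir / "peaks.narrowPeak",
        companion_b=outdir / "companion_b.narrowPeak",
        companion_c=outdir / "companion_c.narrowPeak",
        blacklist=outdir / "blacklist.bed",
        states=outdir / "states.bed",
        modulated_genes=outdir / "modulated_genes.tsv",
        peak_sequences=outdir / "peak_sequences.fa",
        pwms=outdir / "pwms.txt",
        truth_peaks=outdir / "truth_peaks.tsv",
        truth_shared=outdir / "truth_shared.tsv",
    )
    if write_genome:
        io.write_fasta(ws.genome_fasta,
                       {c: bytes(s).decode() for c, s in genome.items()})
    with open(ws.chrom_sizes, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in config.chrom_names:
            fh.write(f"{chrom}\t{config.chrom_length}\n")
    io.write_gene_tsv(ws.genes, genes)
    io.write_narrowpeak(ws.peaks, peaks + decoys)
    io.write_narrowpeak(ws.companion_b, set_b)
    io.write_narrowpeak(ws.companion_c, set_c)
    io.write_bed(ws.blacklist, blacklist)
    io.write_states_bed(ws.states, states)
    io.write_gene_list(ws.modulated_genes, up, down)
    io.write_fasta(ws.peak_sequences,
                   extract_peak_sequences(genome, peaks + decoys))
    io.write_pwm_text(ws.pwms, builtin_pwms())
    pd.concat([truth, decoy_truth], ignore_index=True).to_csv(
        ws.truth_peaks, sep="\t", index=False)
    shared.to_csv(ws.truth_shared, sep="\t", index=False)
    return ws
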