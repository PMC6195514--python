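"""Readers and writers for the on-disk formats the pipeline touches.

Formats: ENCODE narrowPeak (BED6+4), BED3/BED4, BED12 or TSV gene models,
TSV gene lists, FASTA, JASPAR-style PWM text with a family tag, and TSV
reports.  All readers validate and raise :class:`ParseError` (naming the
line) rather than silently coercing malformed records.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ChromatinStateSegment, GeneModel, GenomicInterval, Peak


class ParseError(ValueError):
    """A malformed record in an input file."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _to_int(path, lineno, value, what):
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


def _to_float(path, lineno, value, what):
    try:
        return float(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {value!r}") from None


# ---------------------------------------------------------------------------
# narrowPeak

def parse_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse an ENCODE narrowPeak (BED6+4) file into peaks, in file order.

    Column 7 is the fold enrichment (signalValue), 8/9 the -log10 p/q,
    10 the summit offset from start (-1 = unknown).
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 10:
            raise ParseError(path, lineno,
                             f"expected 10 tab-separated columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
        start = _to_int(path, lineno, start_s, "start")
        end = _to_int(path, lineno, end_s, "end")
        if start >= end:
            raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
        fe = _to_float(path, lineno, fields[6], "fold enrichment")
        nlp = _to_float(path, lineno, fields[7], "-log10 p")
        nlq = _to_float(path, lineno, fields[8], "-log10 q")
        summit = _to_int(path, lineno, fields[9], "summit offset")
        try:
            peak = Peak(
                interval=GenomicInterval(chrom, start, end),
                name=name,
                fold_enrichment=fe,
                neglog10_p=nlp,
                neglog10_q=nlq,
                summit_offset=None if summit == -1 else summit,
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        peaks.append(peak)
    return peaks


def write_narrowpeak(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\t0\t.\t"
                f"{p.fold_enrichment!r}\t{p.neglog10_p!r}\t{p.neglog10_q!r}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# BED3 / BED4

def parse_bed3(path: str | Path) -> list[GenomicInterval]:
    """Plain intervals (blacklists and the like); extra columns ignored."""
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "expected >= 3 columns")
        start = _to_int(path, lineno, fields[1], "start")
        end = _to_int(path, lineno, fields[2], "end")
        try:
            out.append(GenomicInterval(fields[0], start, end))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def parse_states_bed(path: str | Path) -> list[ChromatinStateSegment]:
    """BED4 with a chromatin-state label in column 4."""
    out: list[ChromatinStateSegment] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(path, lineno, "expected 4 columns (BED4 with state)")
        start = _to_int(path, lineno, fields[1], "start")
        end = _to_int(path, lineno, fields[2], "end")
        try:
            out.append(ChromatinStateSegment(GenomicInterval(fields[0], start, end),
                                             fields[3]))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval],
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_states_bed(path: str | Path,
                     segments: Iterable[ChromatinStateSegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state}\n")


# ---------------------------------------------------------------------------
# Gene models

_GENE_TSV_HEADER = ["gene_id", "chrom", "strand", "start", "end", "exons"]


def parse_gene_table(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12 or the package's TSV layout (auto-detected).

    The TSV layout has a header ``gene_id chrom strand start end exons``
    where ``exons`` is a comma-separated list of ``start-end`` blocks
    (absolute coordinates) or empty.  BED12 is detected by its 12
    unlabelled columns.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.split("\t")[:2] == _GENE_TSV_HEADER[:2]:
        return _parse_gene_tsv(path)
    return _parse_gene_bed12(path)


def _parse_gene_tsv(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[:2] == _GENE_TSV_HEADER[:2]:
            continue
        if len(fields) != 6:
            raise ParseError(path, lineno, f"expected 6 columns, got {len(fields)}")
        gene_id, chrom, strand = fields[0], fields[1], fields[2]
        start = _to_int(path, lineno, fields[3], "start")
        end = _to_int(path, lineno, fields[4], "end")
        exons = []
        if fields[5]:
            for block in fields[5].split(","):
                if not block:
                    continue
                try:
                    bs, be = block.split("-")
                except ValueError:
                    raise ParseError(path, lineno,
                                     f"malformed exon block {block!r}") from None
                exons.append(GenomicInterval(chrom,
                                             _to_int(path, lineno, bs, "exon start"),
                                             _to_int(path, lineno, be, "exon end")))
        try:
            genes.append(GeneModel(gene_id, chrom, strand,
                                   GenomicInterval(chrom, start, end),
                                   tuple(exons)))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return genes


def _parse_gene_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 12:
            raise ParseError(path, lineno,
                             f"expected 12 BED12 columns, got {len(fields)}")
        chrom, name, strand = fields[0], fields[3], fields[5]
        start = _to_int(path, lineno, fields[1], "start")
        end = _to_int(path, lineno, fields[2], "end")
        n_blocks = _to_int(path, lineno, fields[9], "blockCount")
        sizes = [_to_int(path, lineno, s, "blockSize")
                 for s in fields[10].rstrip(",").split(",")] if fields[10].strip(",") else []
        starts = [_to_int(path, lineno, s, "blockStart")
                  for s in fields[11].rstrip(",").split(",")] if fields[11].strip(",") else []
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(path, lineno, "blockCount does not match block lists")
        exons = tuple(
            GenomicInterval(chrom, start + bs, start + bs + sz)
            for bs, sz in zip(starts, sizes)
        )
        try:
            genes.append(GeneModel(name, chrom, strand,
                                   GenomicInterval(chrom, start, end), exons))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return genes


def write_gene_tsv(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_HEADER) + "\n")
        for g in genes:
            blocks = ",".join(f"{e.start}-{e.end}" for e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                     f"{g.span.start}\t{g.span.end}\t{blocks}\n")


# ---------------------------------------------------------------------------
# Gene lists (modulated genes)

def parse_gene_list(path: str | Path) -> tuple[set[str], set[str]]:
    """TSV of ``gene_id <tab> direction`` with direction in {up, down}.

    Returns (up, down) gene-id sets; a header line ``gene_id\tdirection``
    is tolerated.
    """
    up: set[str] = set()
    down: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "gene_id":
            continue
        if len(fields) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        gene_id, direction = fields
        if direction == "up":
            up.add(gene_id)
        elif direction == "down":
            down.add(gene_id)
        else:
            raise ParseError(path, lineno, f"direction must be up/down, got {direction!r}")
    if up & down:
        raise ParseError(path, 0, f"genes listed both up and down: {sorted(up & down)[:5]}")
    return up, down


def write_gene_list(path: str | Path, up: Iterable[str], down: Iterable[str]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sorted(up):
            fh.write(f"{g}\tup\n")
        for g in sorted(down):
            fh.write(f"{g}\tdown\n")


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> uppercase-sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(path, 0, f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PWM text

def parse_pwm_text(path: str | Path, pseudocount: float = 0.01):
    """JASPAR-style count matrices with a family tag.

    Each record is a header ``>motif_id family`` followed by four lines
    ``A [ 4 19 0 ... ]`` (brackets optional) in A, C, G, T order.
    Returns a list of :class:`~peakcalibre.motifs.PWM`.
    """
    from .motifs import PWM, pwm_from_counts  # deferred: avoid import cycle

    pwms: list[PWM] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}
    header_line = 0

    def _flush(lineno):
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in "ACGT" if b not in rows]
        if missing:
            raise ParseError(path, lineno, f"motif {header[0]}: missing rows {missing}")
        lengths = {len(rows[b]) for b in "ACGT"}
        if len(lengths) != 1:
            raise ParseError(path, lineno, f"motif {header[0]}: ragged count rows")
        counts = [rows[b] for b in "ACGT"]
        try:
            pwms.append(pwm_from_counts(header[0], header[1], counts,
                                        pseudocount=pseudocount))
        except ValueError as exc:
            raise ParseError(path, header_line, str(exc)) from None
        header, rows = None, {}

    last = 0
    for lineno, line in _data_lines(path):
        last = lineno
        if line.startswith(">"):
            _flush(lineno)
            parts = line[1:].split()
            if len(parts) < 2:
                raise ParseError(path, lineno, "header needs '>id family'")
            header = (parts[0], parts[1])
            header_line = lineno
            continue
        if header is None:
            raise ParseError(path, lineno, "count row before any header")
        tokens = line.replace("[", " ").replace("]", " ").split()
        base = tokens[0].rstrip(":").upper()
        if base not in "ACGT" or len(base) != 1:
            raise ParseError(path, lineno, f"row must start with A/C/G/T, got {tokens[0]!r}")
        try:
            rows[base] = [float(t) for t in tokens[1:]]
        except ValueError:
            raise ParseError(path, lineno, "non-numeric count") from None
    _flush(last + 1)
    return pwms


def write_pwm_text(path: str | Path, pwms) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.family}\n")
            for bi, base in enumerate("ACGT"):
                counts = " ".join(f"{c:g}" for c in pwm.counts[:, bi])
                fh.write(f"{base} [ {counts} ]\n")


# ---------------------------------------------------------------------------
# TSV reports

def write_tsv_report(path: str | Path, rows: Iterable[dict], columns: Sequence[str]) -> None:
    """A plain TSV with a fixed column order; values formatted via ``str``."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t",
                                lineterminator="\n", extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
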