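# peakcalibre

Expression-guided prioritization of transcription-factor ChIP-seq peaks,
built around the downstream analysis of ETV6 binding in t(12;21)
pre-B leukemia cells: which of the thousands of called peaks are strong
enough to matter, and what distinguishes them?

ETV6 is an ETS-family transcriptional repressor lost in the most common
childhood leukemia translocation. A ChIP-seq experiment in cells
re-expressing it yields peak calls of very uneven strength, and the
interesting analysis happens *after* peak calling. This package
implements that downstream pipeline for anyone with narrowPeak calls, a
gene annotation and a differential-expression gene list:

- **QC filtering** — drop peaks overlapping blacklisted regions, with
  fold enrichment above 50 (pileup artifacts), or q-value above 0.1.
- **Threshold calibration** — for each fold-enrichment cutoff
  *t* ∈ {3.0, 3.1, …, 7.0}, associate peaks with FE ≥ *t* to their
  closest TSS and test the resulting gene set for enrichment of known
  expression-modulated genes with a one-sided Fisher exact test
  (hypergeometric tail).  With *k* of *K* modulated genes peak-associated
  out of *n* peak-associated genes in a universe of *N*:

  p(t) = P(X ≥ k),  X ~ Hypergeometric(N, K, n).

  The selected threshold *t\** minimizes p(t).
- **Annotation** — closest-TSS gene per peak (summit-based, unstranded
  distance), genomic categories (exon / intron / proximal ≤ 2 kb /
  distal 2–10 kb / 5d 10–100 kb upstream / other), and the ±10 kb TSS
  distance profile.
- **Motif classes** — log-odds PWM scanning of peak sequences on both
  strands (hit = score ≥ 0.8 × maximum), four-way classification by
  ETS/RUNX motif content, class-fraction-vs-threshold curves, pooled
  two-sample *t* tests of fold enrichment between classes, and the
  ETS-IRF compound motif among motif-free peaks.
- **Cross-cell-line comparison** — per-reference-set Venn counts
  (≥ 1 bp overlap) against two companion peak sets, and chromatin-state
  assignment (15-state coreMarks segmentation, maximal-overlap rule)
  split by shared/specific status.
- **Synthetic data** — a fully seeded generator that emulates every
  input with planted ground truth (motif classes with class-dependent
  fold-enrichment distributions, an expression coupling switching at
  FE 4.5, planted overlap fractions and chromatin-state biases), so the
  whole pipeline is testable end to end without downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
workspace (seed 1, 2,000 peaks + 20 QC-violating decoys on a 4 × 2 Mb
genome with 3,000 genes):

```bash
python analysis/01_simulate.py
python analysis/02_filter_and_annotate.py
python analysis/03_calibrate_threshold.py
python analysis/04_compare_cell_lines.py
python analysis/05_motif_classes.py
```

`03_calibrate_threshold.py` prints:

```
modulated genes: 180 up + 261 down of 3000 total
selected threshold: FE >= 4.5
  peaks retained:     1090
  genes associated:   875 (29.17% of universe)
  modulated overlap:  428 (97.05%)
  enrichment ratio:   3.33
  Fisher p:           9.187e-248
```

The sweep recovers exactly the fold-enrichment value (4.5) at which the
generator switched the gene-modulation probability from 1% to 50% — the
calibration logic finds the planted change point. `05_motif_classes.py`
then shows the planted class structure:

```
motif classes:
  ETS_ONLY     642  (32.1%)
  RUNX_ONLY    321  (16.1%)
  ETS_RUNX     314  (15.7%)
  NEITHER      723  (36.1%)
ETS-containing fraction rises from 0.55 at FE>=3.0 to 0.75 at FE>=7.0
ETS-containing vs motif-free fold enrichment: t=16.14, p=1.35e-54 (means 6.95 vs 4.46)
```

i.e. classification recovers the planted 30/17/15/38 priors, and peaks
carrying an ETS motif are significantly stronger — the planted analogue
of direct ETS-driven binding versus indirect recruitment.

The same pipeline is available as a CLI
(`peakcalibre simulate|filter|calibrate|annotate|compare|motifs|report|run-all`),
each subcommand taking a YAML config (`--config`) and an output
directory (`--out`); `run-all` writes the complete TSV + JSON report
bundle and is byte-for-byte reproducible for a fixed seed and config.

## Layout

```
src/peakcalibre/    library: core, io, peaks, calibration, motifs,
                    comparative, simulate, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property and acceptance tests)
scripts/            acceptance.py
docs/methods.md     model, parameters, numerical choices, limitations
```
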