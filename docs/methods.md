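# Methods

## Coordinate and overlap conventions

All coordinates are 0-based, half-open (`[start, end)`, BED convention),
in memory and on disk. "Overlap" always means sharing at least one base
pair; abutting intervals do not overlap, and no reciprocal-fraction
requirement is applied anywhere (this matches the default behaviour of
the standard interval-intersection tools). Chromosome names are matched
by exact string equality — no `chr` prefix normalization — and the
pipeline logs a warning listing names present in one input but not
another rather than guessing.

A peak's *effective summit* is its reported summit (narrowPeak column
10, relative to start) or, when the summit is unknown (`-1`), the
integer midpoint `floor((start+end)/2)`. All point-based computations
(TSS distance, category assignment, chromatin-state tie-breaking, motif
summit-centering) use the effective summit.

## QC filtering

A peak is discarded if its fold enrichment is *strictly above* the cap
(default 50 — a peak at exactly 50 is kept), if its q-value exceeds the
cutoff (default 0.1, i.e. −log10 q < 1), or if it shares ≥ 1 bp with
any blacklist interval. Multiple blacklists are treated as a plain
union of intervals. A peak failing several checks is logged once under
the first failing reason (fe_cap, then q_max, then blacklist) so the
rejection ledger partitions the input exactly; the filter is idempotent.

## Closest-TSS association and genomic categories

Each peak maps to the gene whose TSS minimizes the unstranded absolute
distance to the effective summit. The minus-strand TSS is the last
covered base of the gene span (`end − 1`). Equidistant ties (including
several genes sharing one TSS position) resolve to the
lexicographically smallest gene id — deterministic and independent of
input order. Peaks on chromosomes without genes are flagged unassigned.
The signed distance is negative when the summit lies upstream of the
TSS *relative to the gene's strand*.

The summit-based distance is a deliberate standardization: the two
annotation tools commonly used for this step measure from the peak
center and from peak edges respectively, so peak-level agreement with
any one of them is approximate by construction.

Category assignment gives genic locations precedence: a summit inside
any gene body is EXON (if inside an exon of a covering gene) or INTRON;
otherwise the upstream distance to the closest TSS is binned as
PROXIMAL (≤ 2 kb), DISTAL (≤ 10 kb) or FIVE_D (≤ 100 kb); summits
downstream of their closest gene, or farther than 100 kb upstream, are
OTHER. The bins are nested and applied in order, so the six categories
partition the peak set. The ±10 kb TSS profile uses half-open bins of
1 kb on the signed distance (`floor(d / bin)`), so a distance of
exactly +10 kb is excluded and −10 kb included.

A peak is *expression-correlated* iff its closest gene belongs to the
modulated (up ∪ down) set.

## Threshold calibration

For each grid value *t* (default 3.0–7.0 in 0.1 steps, generated by
integer index `t = 3.0 + i·0.1` to avoid floating-point accumulation;
comparisons are inclusive, FE ≥ *t*), the peaks passing *t* define a
set of *n* closest genes, of which *k* belong to the *K* modulated
genes, in a universe of *N* genes. The one-sided ("greater") Fisher
exact test on the 2×2 table

|            | modulated | not modulated |
|------------|-----------|---------------|
| with peak  | k         | n − k         |
| without    | K − k     | N − K − n + k |

equals the hypergeometric upper tail P(X ≥ k), evaluated through the
scipy survival function (log-space internally; accurate for N ≈ 60,000
and p-values below 1e−300). Modulated genes are kept inside the
universe margin — the standard Fisher construction; excluding them from
the background is a defensible alternative reading of the original
phrasing, would change the p-value only marginally at these margins,
and is not the default. A two-sided variant is available behind a flag.

The selected threshold is the grid argmin of the p-value, ties broken
toward the *larger* (more stringent) threshold. No multiple-testing
adjustment is applied across the grid: the procedure selects a minimum,
it does not report the minimum as a calibrated significance level.

Reported percentages are kept at full precision; rounding is a
formatting concern of the report writers (published values of this kind
mix truncation and rounding, so the acceptance checks accept either
rendering at printed precision).

## Motif scanning and classes

PWMs are parsed from JASPAR-style count text with a family tag
(ETS, RUNX, IRF, ETS_IRF_COMPOUND, OTHER); counts are column-normalised,
a pseudocount of 0.01 is added and renormalised, so all probabilities
are positive. Scoring is the log-odds sum log(p_i(base)/0.25) against a
uniform background (no GC correction — simple, documented, swappable);
an `N` base contributes 0. A window is a hit when its score reaches a
configurable fraction (default 0.8) of the motif's maximum achievable
score; the minus strand scores the reverse complement of each window
and reports the window's plus-strand offset. This replaces de-novo
motif discovery: the bundled example library carries sharp consensus
models for the ETS site (GGAA core), the RUNX site (TGTGGT core), an
ISRE-style IRF site and a single ETS-IRF compound element. The compound
element's internal geometry (half-site spacing) is modelled as one PWM
with an `N` spacer position; modelling it as two half-sites with a
spacing constraint is the obvious refinement and deliberately out of
scope.

Peaks are classified ETS_RUNX / ETS_ONLY / RUNX_ONLY / NEITHER by the
presence of ≥ 1 hit from each family; the ETS-IRF compound is tracked
as a separate flag and reported for NEITHER peaks. Motif enrichment
versus shuffled sequences (mononucleotide shuffle, empirical p with
+1 continuity correction) is available as a stand-in for a discovery
tool's ranking statistic; it is off by default in the pipeline
(`enrichment_shuffles: 0`) because 100 shuffles of every peak sequence
dominate the runtime of an otherwise sub-second stage.

The "Student's t test" between class fold-enrichment groups is the
classical pooled-variance two-sample t (that is the test the name
denotes), with Welch available behind a flag; each group's report
carries the 5th/95th percentiles and median for whisker plots. When
both groups have zero variance the convention is p = 1 for equal means
and p = 0 otherwise.

## Cross-cell-line comparison and chromatin states

Venn counts are per reference set: count(X→Y) is the number of X peaks
overlapping ≥ 1 Y peak. This is intentionally asymmetric — two X peaks
hitting one Y peak count twice from X's perspective and once from Y's —
because that is how region-set overlaps are reported in practice, and
the only convention consistent with published tallies that quote
different numerators for each set. The shared/specific partition used
for chromatin-state analysis takes "shared" = primary peaks overlapping
≥ 1 reference-set peak.

Each peak's chromatin state is the 15-state coreMarks label with
maximal bp overlap; ties go to the state covering the effective summit;
a peak overlapping no segment falls back to Quies and increments a
warning counter. Per-subset state fractions are probability vectors
over the fixed 15-label vocabulary. No enrichment test is attached to
the state distributions; the pipeline reports fractions only.

## Synthetic data generator

The generator emulates the study's inputs at desk scale with planted
ground truth. Defaults (the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| genome | 4 chromosomes × 2 Mb | smallest size that keeps 2,000 non-overlapping peaks and 3,000 genes at realistic density |
| n_genes | 3,000 | one gene per ~2.7 kb; the gene universe for calibration |
| n_peaks | 2,000 | the scale of a focused TF ChIP-seq peak set |
| class priors | 0.30 / 0.17 / 0.15 / 0.38 (ETS_ONLY / RUNX_ONLY / ETS_RUNX / NEITHER) | the 38% motif-free fraction is the anchored value; the rest are plausible stand-ins |
| log-FE means | ln 6 (ETS-containing), ln 4 (others), σ = 0.5 | plants the "ETS-containing peaks are stronger" structure with realistic overlap between classes |
| coupling | t0 = 4.5, base rate 0.01, boosted rate 0.5 | a gene is modulated w.p. 0.5 if its best peak has FE ≥ 4.5, else w.p. 0.01; up:down split 59:88 |
| companion overlap | p_AB = 0.19, p_AC = 0.048, p_ABC = 0.035 | the published overlap fractions, used as planted probabilities |
| state bias | 0.9 shared → TssAFlnk/Enh, 0.9 specific stays Quies | plants the shared-vs-specific chromatin separation |
| motif offsets | Gaussian(0, 40 bp) around the summit | summit-centered planting, consensus instances, random strand |
| peak widths | uniform 200–500 bp, non-overlapping placement | typical narrow TF peaks |
| decoys | 20 QC-violating peaks (FE > 50 or blacklist overlap) | gives the filter stage real work on the default workspace |

One global seed fans out to fixed per-stage child streams
(`SeedSequence((seed, stage_id))`), so stages can be regenerated
independently and every output file is byte-identical across runs.
Blacklist intervals and companion-set padding peaks are
rejection-sampled away from the primary peaks, so planted overlap
fractions and QC outcomes are exactly recoverable. Motifs are planted
at exact consensus by default; a mutation-rate knob exists to stress
the scanner.

What the generator does *not* emulate: read-level noise (no FASTQ/BAM),
fragment-size effects, GC or mappability bias, correlated peak
placement (real peaks cluster at promoters), realistic gene-density
heterogeneity, and motif instances in background sequence beyond what
uniform-random DNA produces. Passing tests therefore demonstrate that
the *analysis logic* recovers planted structure, not that the pipeline
is robust to every artifact of real data.

Because genes are dense on the small synthetic genome, every peak lies
within 10 kb of some TSS and most summits fall inside gene bodies; the
genomic-category and TSS-profile stages are exercised for correctness,
not for realistic category frequencies.

## Numerical and design choices

- Overlap queries use merged sorted subject intervals with a single
  bisect per query; brute-force all-pairs oracles verify equality on
  random fixtures in the test suite.
- The Fisher grid tie rule (larger threshold) makes the degenerate
  all-peaks-identical case deterministic.
- Fractions over an empty selection (a threshold retaining zero peaks,
  a ratio with zero denominator) are reported as NaN sentinels, never
  silently dropped.
- The pipeline's summary counts are re-derived from the written TSVs in
  a verification pass that fails the run on any mismatch; reports
  contain no timestamps, so a rerun is byte-identical.
- The monotone-trend check on the ETS-containing fraction versus
  threshold is operationalised as Spearman ρ ≥ 0.9 plus a bounded
  per-step decrease (0.02): at 2,000 peaks the per-0.1-step sampling
  noise of the empirical curve is comparable to its true slope, so
  strict step-wise monotonicity is not an informative criterion at this
  sample size.

## Problem sizes

The test suite and acceptance script run the generator at 300 peaks for
pipeline-level contracts and 2,000 peaks for the statistical recovery
experiments (threshold recovery over 20 seeds, motif-class recovery,
class FE tests), the sizes at which those properties are stated.

## Known limitations

- Exact peak-level reproduction of published gene lists from real data
  is not expected: the original TSS-distance convention (summit- vs
  edge-based) and tie-breaking are unspecified, and the exact 2×2 table
  behind the published p-value is ambiguous — the implementation
  documents one defensible choice for each and exposes alternatives
  where they matter.
- Multi-gene assignment (all genes within a window), enhancer–gene
  linking models and promoter databases are out of scope; each peak has
  exactly one closest gene.
- PWM scanning with a fraction-of-maximum cutoff is cruder than
  per-motif calibrated thresholds; with the sharp bundled consensus
  models at the 0.8 default it admits essentially only exact matches.
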