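# Methods

## The analysis model

The pipeline operates on gene-keyed differential tables: one row per gene per
condition-vs-mock comparison, with mean normalized reads for each group, a
log2 fold change and a raw p-value. Four timepoints (d0, d3, d12, d28) form
the time course; each is an independent comparison against mock cells. All
downstream statistics are deterministic set arithmetic on these tables —
there is no model fitting and no sampling in the analysis itself.

**Signature filter.** A gene is a member of the up (down) signature iff
reads > `min_reads` AND p < `max_p` AND log2FC > `min_abs_log2fc`
(< −`min_abs_log2fc`). Defaults: 10 reads / 0.05 / 2 for expression and
2 reads / 0.05 / 1 for accessibility. Inequalities are strict by default
because that is how the thresholds are written; a `strict=False` flag
switches to ≥/≤ since existing supplementary tables may have been produced
either way. The reads predicate is evaluated on the *higher* of the two group
means by default (so a gene silent in mock can still pass); `mock`,
`condition` and `mean_of_means` bases are selectable. Raw p-values are used —
the filter predates multiple-testing correction — with an optional
Benjamini–Hochberg mode that is off by default. An infinite log2FC passes the
magnitude predicate; a missing p-value excludes the gene and is counted in
the log.

**GUDC.** For signature S in universe U (all gene entries of that
timepoint's table — the universe is per-timepoint, not a fixed genome
annotation), usage_c = 100·|S_c|/|U_c| per chromosome and
mean = 100·|S|/|U|; the fingerprint is deviation_c = usage_c − mean.
Chromosome Y and unplaced genes are dropped from both sets (counted and
logged); MT is kept by default because the signatures of interest are
mitochondria-heavy, with a flag to exclude it. The identity
Σ_c |U_c|·deviation_c = 0 holds exactly and is asserted in tests. Note that
for a signature drawn uniformly at random, the absolute deviations are
hypergeometric sampling noise whose pp-scale grows with mean usage; the
quantity that vanishes with signature size is the deviation *relative to the
mean usage* (and deviations vanish identically at saturation).

**DAGT.** Gene types are a fixed eight-class taxonomy (pseudogene,
non_annotated, lincRNA, miRNA, snoRNA, mitochondrial, protein_coding, other).
Ensembl/GENCODE biotypes are folded onto it (`*_pseudogene` → pseudogene,
`lncRNA`/`lincRNA` → lincRNA, …, everything unrecognized → other);
"non-annotated" means no biotype was available. Two total policies make the
classes a partition: a gene absent from the annotation is non_annotated on
chromosome "other", and any gene on MT is mitochondrial regardless of
biotype (MT precedence — classes stay mutually exclusive). Reads are summed
on the same basis used by the filter, so class read totals add up exactly to
the signature total. Class membership is annotation-build-dependent; the
annotation source is recorded in the breakdown metadata.

**DAGE/ST.** The discriminator log2_var = ln(cond/mock)/ln 2 is evaluated
with sentinels: +∞ when mock = 0 < cond (de novo transcribed), −∞ when
cond = 0 < mock (shut down), undefined (NaN) when both are zero — such genes
belong to neither set. "Zero" means an exact zero in the mean-reads field;
when raw count matrices are available the generator/upstream guarantee is
that a zero group mean implies all-replicate zeros, so averaging cannot
fabricate zeros. An optional floor on the expressed side
(`min_de_novo_reads`, default 0) is available; de novo/shut-down sets are
*not* intersected with the stringent signatures — these genes sit at very low
read counts and fail the reads predicate. Tracing orders the per-timepoint
flagged sets, labels each gene with its first appearance and computes
persistence(o→t) = |first_o ∩ flagged_t|/|first_o|; the counting identity
|flagged_t| = Σ_{o≤t} |first_o|·persistence(o→t) holds by construction and
is asserted on every run.

**MACE↔ATAC.** Matching is by gene id (peak-to-gene assignment is upstream
and out of scope). Duplicate accessibility entries per gene are resolved by
largest |log2FC| (logged). Attribution is by the sign of the (optionally
filter-passing) ATAC log2FC, with an explicit zero bucket so the partition is
total; concordance is the fraction of signature genes found in the ATAC data
at all. Maintained fractions delegate to the same |early ∩ late|/|early|
arithmetic as signature tracing. Circos exports use synthetic ordinal
coordinates (the gene's index along its chromosome) because the pipeline
carries no genomic intervals.

## The substitute differential test

For synthetic end-to-end runs the package normalizes raw counts by
median-of-ratios — factor_j = median over all-positive genes of
count_ij / geometric-mean_i, with a pseudo-reference fallback (nonzero-entry
geometric means) behind an explicit flag — and tests each gene by Welch's t
on log2(x+1)-transformed replicate values (p missing when either group has
one replicate; exactly equal replicate vectors give p = 1). Fold changes use
no pseudocounts; zero group means produce the signed-infinity sentinels the
detector consumes. This test is deliberately simple: reproduction of
published analyses ingests the study's own DESeq2 statistics, and everything
downstream consumes only (reads, log2FC, p). Dispersion shrinkage, Wald/LRT
tests and independent filtering are out of scope.

Because the per-gene reference is the geometric mean of the samples
themselves, size factors are defined up to one common positive scale:
rescaling a column by c multiplies its factor by c *relative to the others*
(every factor also moves by a common c^(−1/m)), and normalized counts are
invariant up to one common constant. Under the null the test's p-values are
uniform to KS distance < 0.05 at 10,000 genes and 3+3 replicates (verified
by simulation); this holds for moderate means (≥ ~50) where the
log-transformed NB is near-normal.

## The synthetic generator

The generator emulates the study conditions; its defaults are those
conditions and are set once.

- **Universe.** 45,455 genes (the size implied by a 50-gene signature with a
  0.11 % mean usage) with biotype proportions protein-coding 0.40,
  pseudogene 0.28, lincRNA 0.09, miRNA 0.03, snoRNA 0.015,
  non-annotated 0.14, other ≈0.044, plus 37 mitochondrial genes carrying the
  human MT gene symbols. Type counts use largest-remainder rounding (ties by
  type name); chromosomes 1–22 and X are assigned by realistic density
  weights, MT exclusively to mitochondrial genes, and Y is absent.
  Per-timepoint expressed universes are 45,455 / 32,347 / 43,636 / 31,000
  gene entries: the d0 and d3 sizes are implied by the published mean usages
  (0.11 % of the d0 table for 50 genes, 1.96 % of the d3 table for 634), the
  d12 size keeps the day-12 usage at the d0-like level the time course
  describes, and the d28 size is a one-time choice in the 30k–45k range.
- **Planted signatures.** Per timepoint and direction, gene-type blocks with
  the published member counts and read totals (e.g. day-0 up: 15 pseudogenes
  33,058 reads … 17 mitochondrial 305,728 reads); where published class
  tallies fall short of the printed signature size the difference is padded
  with non-annotated members at nominal reads. Planted log2 effects are ±4
  (mean-read fields: the favoured group carries the class mean, the other
  group that mean/2⁴). The d28 up-signature reuses 418 of the d3 members
  (mitochondrial members recur via a shared pool prefix; the remainder is
  apportioned across shared classes by largest remainder); down signatures
  are idiosyncratic across timepoints.
- **De novo / shut-down cohorts.** Per-timepoint flagged totals
  (2221/3803/2119/3672 de novo; 3957/3171/3964/2973 shut down) are realized
  as first-appearance cohorts with a per-step retention of 0.5 — the largest
  simple fraction compatible with the totals (the de-novo series requires
  ≤ 0.557) — using nested prefixes, so a dropped gene stays dropped and the
  set flagged at all four timepoints is the surviving day-0 core; 95
  protein-coding genes are planted in that core. Flagged genes have an exact
  zero in the silent group and a low mean (~0.5–8 reads) in the expressed
  group, keeping them below the signature reads floor.
- **Accessibility tables.** Signature genes are covered by the ATAC table
  with probability 0.93 (exact counts), with change sign matching the
  expression direction at coupling 0.9 (exact counts), |log2FC| ~ U(1.2, 3)
  and p < 0.04 so covered genes pass the accessibility filter; an
  800-gene deregulated background and 10,000 null rows are added. A second
  accessibility experiment plants early/late signature pairs of 500 genes
  with 101, 31 and 23 recurring (the three construct conditions), sizes
  chosen to realize the published maintained fractions exactly.
- **Two output paths, one ground truth.** `generate_diff_tables` writes the
  planted expectations directly into the mean-read fields (null genes get
  log-uniform baselines on (20, 2000), a N(0, 0.15) log2 shift and uniform
  p-values), so the deterministic downstream arithmetic reproduces the
  planted numbers exactly. `generate_counts` draws NB(mean, dispersion 0.05)
  replicate counts (Poisson below dispersion 1e-12) with per-sample library
  factors from U(0.7, 1.4) — replicate depth is not published; this spread is
  an assumption — and guarantees the planted zero patterns exactly by
  bumping one replicate to 1 in any group left all-zero that was not planted
  silent.

**What the generator does not emulate:** read-level data (no raw reads,
UMIs, or fragment-level ATAC peaks), batch effects, gene-gene correlation,
realistic DESeq2 p-value/fold-change shrinkage behaviour, annotation
ambiguity, or overdispersion heterogeneity across genes. Passing tests
therefore demonstrate that the analysis arithmetic is correct and that the
planted study-scale structure is recovered end-to-end — not that the
upstream differential-expression step would behave identically on real
sequencing data.

## Numerical conventions

- Strict inequalities in the filter by default; thresholds echoed to the run
  summary for provenance.
- Signed-infinity log2FC sentinels are first-class values through I/O
  (TSV round-trips "inf"/"-inf"); both-zero genes carry NaN and are excluded
  from both flagged sets.
- Tolerant numeric parsing: in integer-like columns both "33,058" and
  "33.058" are thousands-separated integers; a single decimal comma is
  accepted when unambiguous; unparseable rows are dropped with their row
  numbers reported.
- p = 0 maps to a capped −log10 p (default 310) in the volcano export.
- Venn regions are computed by exact id set algebra and partition the union.
- Duplicate ATAC entries: keep largest |log2FC|, deterministic after a
  stable sort by gene id.
- All randomness flows from one integer seed through named
  `numpy.random.default_rng([seed, stage])` streams; identical configuration
  and inputs give byte-identical outputs (hash-checked).
- Largest-remainder apportionment breaks remainder ties by name order.

## Problem sizes used in the checks

The test suite exercises a scaled-down configuration (3,000 genes,
2.4k–3k-gene universes, tens-of-genes signatures) for speed and the full
study-condition configuration (45,455 genes) once per session for the
reproduction checks; the acceptance script always runs the study-condition
configuration.

## Known limitations

- The published class tallies do not always sum to the printed signature
  totals; the generator pads with non-annotated members, so per-class
  non-annotated counts at d3/d28 are approximate while headline sizes and the
  mitochondrial block are exact.
- The heatmap union of protein-coding signature members is not constrained
  to any published size: the printed per-class protein-coding counts cannot
  reach the published figure-level union (608), so the export reports
  whatever the signatures contain.
- Concordance and attribution percentages on synthetic data reflect the
  configured coverage/coupling, not any timepoint-specific chromatin
  biology; the paired tables carry one coupling value for all timepoints.
- The reference group for later timepoints is always mock; comparing d3+
  samples against d0 cells instead is possible upstream but is not a
  pipeline mode.
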