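# reciprotrace

Downstream analysis of a t(4;11) fusion-gene time-course: given per-timepoint
differential-expression result tables (condition vs mock; DESeq2-style columns
for mean normalized reads per group, log2 fold change and p-value) and matched
gene-keyed ATAC accessibility tables, the package computes

- **signatures** — the stringent three-predicate filter
  (reads > 10, *p* < 0.05, |log2FC| > 2; accessibility variant
  reads > 2, |log2FC| > 1) per timepoint and direction, plus exact Venn
  overlap structure between timepoints;
- **GUDC** (*gene usage on different chromosomes*) — a chromosome fingerprint:
  per chromosome c, usage_c = 100·|S_c|/|U_c| against the mean usage
  100·|S|/|U| of signature S in the expressed universe U, reported as the
  deviation usage_c − mean (chromosome Y excluded);
- **DAGT** (*differential analysis by gene type*) — the partition of a
  signature into pseudogene / non-annotated / lincRNA / miRNA / snoRNA /
  mitochondrial / protein-coding / other classes with member counts and
  summed reads, plus read profiles of named mitochondrial genes;
- **DAGE/ST** (*de novo & shut-down detection, signature tracing*) — the
  log2_var discriminator ln(FC)/ln 2 with signed-infinity sentinels flags
  genes with exactly zero mock reads (de novo) or zero condition reads
  (shut down); flagged sets are traced over the timepoint order with
  first-appearance labels and per-origin persistence fractions;
- **MACE↔ATAC concordance** — each transcriptional target is matched by gene
  id against the accessibility table and attributed to accessible
  (ATAC log2FC > 0) or less accessible (< 0) chromatin; maintained-chromatin
  fractions 100·|early ∩ late|/|early| compare early and late accessibility
  signatures.

An optional upstream stage normalizes raw count matrices by the
median-of-ratios (geometric-mean) method and supplies a simple Welch-t
substitute test on log2(x+1) replicate values, so fully synthetic runs work
end-to-end without external differential-expression output.

A seeded synthetic-data generator (`reciprotrace.synthetic`) emulates the
study design — a d0/d3/d12/d28 time course with 3 replicates, a 30k–45k gene
universe, negative-binomial counts, planted up/down signatures with a large
d3/d28 overlap, traced de novo/shut-down cohorts, and coupled accessibility
tables — and returns the planted ground truth alongside, so every downstream
stage is testable against known answers.

## Worked example

```python
from reciprotrace import (SyntheticConfig, generate_diff_tables,
                          filter_signature, breakdown, fingerprint,
                          detect_de_novo, usage_fold_change)
from reciprotrace import gudc

tables, atac, maintenance, truth = generate_diff_tables(SyntheticConfig(seed=1))

up_d0 = filter_signature(tables["d0"], direction="up", timepoint="d0")
up_d3 = filter_signature(tables["d3"], direction="up", timepoint="d3")
print(len(up_d0), len(up_d3))                     # 50 634

bd = breakdown(up_d0)
print(bd.n("mitochondrial"), bd.reads("mitochondrial"))   # 17 305728.0

fp0 = fingerprint(up_d0, tables["d0"])
fp3 = fingerprint(up_d3, tables["d3"])
print(round(fp0.mean_usage_pct, 2), round(fp3.mean_usage_pct, 2),
      round(usage_fold_change(fp0, fp3), 1))      # 0.11 1.96 17.8

print(len(detect_de_novo(tables["d0"])))          # 2221
```

Reading the output: the day-0 up-signature (constitutive fusion protein
alone) holds 50 genes, 17 of them mitochondrial carrying ~306k reads; the
day-3 signature (both fusion proteins co-expressed) expands to 634 genes,
lifting the mean chromosome gene usage from 0.11 % to 1.96 % of the expressed
universe (≈18-fold); 2,221 genes are transcribed de novo (zero mock reads) at
day 0.

The same stages are available from the shell:

```sh
reciprotrace simulate --seed 1 --out data/
reciprotrace run --config run.yaml          # full pipeline + JSON summary
reciprotrace filter|gudc|dagt|trace|atac …  # single stages
```

`reciprotrace run` writes signature/fingerprint/breakdown/trace/concordance
tables, the heatmap log2FC matrix and volcano export, Circos-compatible data
files, and a run summary JSON with a content hash per output; identical
inputs and configuration produce byte-identical outputs.

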