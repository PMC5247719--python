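# lncscape

Analysis toolkit for joint coding / long-non-coding transcriptome studies of
bulk RNA-seq time courses, modelled on the design of chronic spinal-cord-injury
experiments in rat (a sham control group and three post-injury time points —
1, 3 and 6 months — with n = 3 biological replicates each).

Starting from count and FPKM matrices plus genome annotations, the package
covers the full downstream arc of such a study:

- **lncRNA catalogue construction** — merge lncRNA annotations from two
  sources (e.g. a curated and a predicted set), dropping transcripts under
  200 nt and cross-source same-strand exonic redundancy.
- **Positional classification** — strand-aware assignment of every lncRNA to
  one of eight classes relative to protein-coding genes (PCGs): intergenic
  convergent/divergent (IC/ID, same/opposite strand as the nearest PCG) and
  genic exonic/intronic/overlapping, each split same-strand vs antisense
  (GES/GEAS, GIS/GIAS, GOS/GOAS), with nearest-neighbor distances and
  exon-structure summaries.
- **Expression QC** — FPKM flooring at 0.1, the "expressed" filter
  (FPKM > 1 in ≥ 1 sample), log2 + quantile normalization, pairwise Pearson
  sample correlation with an average-linkage dendrogram, and replicate
  outlier detection.
- **Differential expression** — a re-implementation of the classic exact
  negative-binomial test for small-replicate count data: median-of-ratios
  size factors, method-of-moments dispersion with a parametric trend
  α(μ) = a₀/μ + a₁ and conservative max(raw, fitted) choice, and the
  conditional exact test summing partition probabilities of the pooled count.
  DEGs require FPKM > 1, fold-change > 2, and BH FDR < 0.01.
- **Temporal clustering + enrichment** — Ward clustering of DEG row
  z-scores, hypergeometric gene-set enrichment per cluster (FDR < 0.05), and
  a redundancy-based choice of the cluster count.
- **Guilt-by-association GSEA** — per-lncRNA correlation-ranked PCG lists
  scored with the weighted Kolmogorov–Smirnov running sum, gene-set
  permutation NES and FDR (flagged at FDR < 0.25).
- **Cis-neighbor pairs** — DE lncRNA / DE PCG neighbor pairs with
  significant expression correlation, filtered on overlap-or-< 5 kb distance.
- **Motif analysis** — regulatory regions (5 kb upstream to 1 kb downstream
  of the TSS), PWM scanning with *exact* p-values from the
  dynamic-programming score distribution, run-wide BH FDR, TF presence
  matrices and TF–lncRNA expression correlation.
- **Cross-species SNP homology** — UCSC-chain lift-over of lncRNA loci to a
  target assembly and intersection with a GWAS/ClinVar-style disease-SNP
  table.
- **Synthetic data** — seeded generators for every input with
  machine-readable planted truth (classes, DE genes, co-expression, motif
  occurrences, chain/SNP placements), so the whole pipeline is testable
  end-to-end without downloads.

## Worked example

Run the full synthetic pipeline (annotation → QC → DE → clustering → GBA →
cis pairs → motifs → SNP homology) from one seed:

```bash
lncscape run --seed 3 --out results_run
```

```
{"config_hash": "fcc1b453a978", "tables": ["cis_pairs", "class_summary",
 "classes", "cluster_enrichment", "clusters", "deg_1M", "deg_3M", "deg_6M",
 "gba", "motif_hits", "snp_report"]}
```

`results_run/classes.tsv` holds one positional call per planted lncRNA:

```
lnc_id	class	partner_pcg_id	distance_bp	n_transcripts
LNC0000	IC	PCG0000	1673	1
LNC0002	IC	PCG0002	4096	1
```

`LNC0000` is intergenic, on the same strand as its nearest protein-coding
gene `PCG0000`, 1,673 bp away — an IC call. The `deg_*` tables list per-gene
fold-changes, exact-test p, BH q and the three-criterion DEG flag per time
point; `gba` holds per-(lncRNA, gene set) ES/NES/FDR; `motif_hits` the
retained PWM hits with exact p and q; `snp_report` the lncRNAs whose
lifted-over loci contain disease SNPs. Rerunning with the same seed
reproduces every table byte-for-byte.

Library use mirrors the CLI; for example, classifying a catalogue:

```python
from lncscape import read_annotation
from lncscape.lnc_classify import classify_catalogue

lncs = read_annotation("catalogue.bed", "BED12")
pcgs = read_annotation("genes.gtf", "GTF", default_biotype="protein_coding")
table, summary = classify_catalogue(lncs, pcgs)
```

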