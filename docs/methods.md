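# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data conditions the package is tested under — including what those
tests do and do not establish about real data.

## Coordinates and annotation model

All coordinates are 0-based half-open internally; GTF/GFF3 I/O converts
from/to 1-based inclusive, BED12 is native. A gene is a set of transcripts
sharing one chromosome, strand and biotype; its span is the union of
transcript spans. Transcripts with exons on mixed strands or with
intra-transcript overlapping exons are rejected at parse time (counted and
logged), which keeps downstream interval arithmetic total.

Catalogue merging removes transcripts with spliced length < 200 nt (the
definitional lncRNA floor; exactly 200 is kept) and then treats ≥ 1 bp of
same-strand exonic overlap between sources as redundancy, keeping the first
("primary") source's transcript. Precedence by argument order makes the
merge deterministic and idempotent.

## Positional classification

The decision cascade for a lncRNA against the protein-coding annotation:

1. **Genic** if the gene spans intersect. Subtype precedence is
   exonic > overlapping > intronic: ≥ 1 bp exon–exon overlap ⇒ GES/GEAS; a
   whole PCG inside one lncRNA intron ⇒ GOS/GOAS; otherwise GIS/GIAS.
   Partial span overlap with neither exon contact nor containment has no
   named class of its own and falls to the intronic subtype.
2. **Intergenic** otherwise, labelled IC (same strand) or ID (opposite
   strand) by the nearest PCG on the chromosome. "Convergent/divergent"
   here follow the strand-identity definition, not the head-to-head
   orientation convention used elsewhere in the literature.

Partner selection among several overlapping PCGs: largest exonic overlap,
then largest span overlap, then smallest TSS distance, then lexicographic
gene id. Intergenic equidistant ties go to the PCG upstream of the lncRNA
relative to the lncRNA's strand. Distance is the gap between closest span
boundaries, zero on touch or overlap; the distance statistics use lncRNA
span → PCG gene span at gene level (transcript-level counts are also
reported by the summary). A chromosome with no PCG yields an IC call with
no partner and an undefined distance rather than an error.

The classifier is verified against a brute-force oracle that enumerates
explicit base-position sets for every span/exon/intron relation; agreement
is exact over thousands of random layouts, including the awkward
partial-overlap geometries the generator does not plant deliberately.

## Expression processing

FPKM values below 0.1 are floored at 0.1 before any ratio is formed
(ratio-inflation guard); a gene is "expressed" when its maximum FPKM is
strictly above 1. Quantile normalization is the mean-rank variant: after
log2, each column's values are replaced by the mean of the per-column
sorted vectors at their (tie-averaged) ranks, so all column order
statistics coincide exactly afterwards. Pearson sample correlation and the
average-linkage Euclidean dendrogram are computed on the normalized values;
flooring precedes the dendrogram.

Outlier detection flags a sample whose mean within-group correlation falls
more than k·SD (default k = 2) below the across-sample mean of that
statistic. The rule is a simple operationalization of "one clearly
discordant replicate"; k is exposed because no principled universal value
exists. On the generator's planted-corruption condition (one
row-shuffled replicate among 12) the flag is essentially always unique and
correct; on real data with milder artefacts the rule is only a screen.

## Differential expression

The test is the conditional exact negative-binomial test for two small
groups of counts:

- **Size factors**: s_j = median over genes of K_ij / (geometric mean of
  gene i across samples), restricted to genes with nonzero counts
  everywhere (a pseudo-reference fallback ignores zeros on request).
- **Dispersion**: normalized counts q_ij = K_ij/s_j; per-gene raw
  dispersion by method of moments, α_raw = (w − μ·mean(1/s)) / μ², with w
  the within-group pooled variance; a parametric trend α(μ) = a₀/μ + a₁ fit
  by least squares over genes with positive raw dispersion; final
  dispersion = max(raw, fitted), floored at 1e-8. The max is deliberately
  conservative for n = 3.
- **Exact test**: conditioned on K_S = K_A + K_B, each condition's sum is
  NB with mean q̂·Σs_j and variance μ + α q̂² Σs_j²; the p-value sums the
  probabilities of all partitions (a, K_S − a) no more likely than the
  observed one (log-space, with a 1+1e-7 tie tolerance; Poisson limit when
  the variance collapses to the mean). The computation is exact — all
  K_S + 1 partitions are summed — and is checked against a literal joint-pmf
  enumeration oracle.

DEG calling conjoins three criteria: expressed (max FPKM > 1), linear
fold-change of floored mean normalized counts > 2 in either direction, and
BH FDR < 0.01 computed over the expressed universe per comparison. The FC
threshold is interpreted on the linear ratio scale (up: FC > 2; down:
FC < 1/2), recorded in the output metadata.

Calibration under the null (5,000 NB genes, μ = 100, α = 0.1, n = 3 vs 3)
gives P(p < 0.05) ≈ 0.035–0.04 — slightly conservative, as expected from
the max(raw, fitted) dispersion. Planted-truth recovery at FC 4 under the
same conditions reaches recall ≥ 0.6 with observed FDR ≤ 0.05 at q < 0.01
across seeds. These figures describe this idealized generative regime;
real libraries with outlier replicates or correlated genes will do worse.

The qPCR utility implements ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt − mean calibrator ΔCt, RQ = 2^−ΔΔCt, with per-group Welch
t-tests on ΔCt against the calibrator (α = 0.05). Welch is used everywhere
a two-sample t-test appears, since equal variances are never guaranteed.

## Clustering and enrichment

DEG profiles are row-z-scored (constant rows map to 0) and clustered by
Ward's method on Euclidean distances; the tree is cut at k clusters.
Gene-set enrichment per cluster is the upper-tail hypergeometric
probability with BH FDR across the collection (enriched at q < 0.05); sets
are intersected with the universe (all expressed genes — the conservative
choice, configurable) before testing.

The cluster count is chosen by enrichment redundancy: for each candidate k,
the mean pairwise Jaccard similarity of the clusters' enriched-set lists.
Redundancy stays near zero while every cluster captures a distinct program
and rises once clusters split one program across two lists, so the **largest
k attaining the minimal score** is selected — the finest non-redundant
clustering. A smallest-k tie-break would degenerately return the bottom of
the candidate range whenever several k are tied at zero.

## Guilt-by-association GSEA

For each DE lncRNA, all PCGs are ranked by Pearson correlation of expression
across all retained samples (constant profiles excluded; ties broken by gene
id). The enrichment score is the weighted KS running sum with weight
exponent p = 1 (the classic weighted default): hits add |r|^p normalized by
the in-set total, misses subtract 1/(N − N_hits); ES is the signed maximum
deviation.

With three replicates per group a phenotype permutation null is impossible,
so significance uses **gene-set permutation**: random same-size sets drawn
from the ranked universe (1,000 permutations by default; 200 in the scaled
test runs). NES divides ES by the mean |ES| of same-sign null scores; the
FDR is the standard NES-ratio estimator (fraction of null NES at least as
extreme over fraction of observed NES at least as extreme), flagged at
FDR < 0.25. Gene-set permutation is known to be anti-conservative relative
to phenotype permutation when genes are strongly co-correlated; flagged
associations on real data are hypotheses, not detections.

## Cis pairs

Candidates are DE lncRNAs whose classified partner PCG is itself a DEG;
Pearson r and p are computed across all retained samples. Filters:
|r| > 0.75, p < 0.01, and span overlap or distance strictly < 5,000 bp.
The r and p thresholds match the TF-correlation criterion used elsewhere in
the workflow and are exposed as parameters.

## Motif scanning

Regulatory regions span 5 kb upstream to 1 kb downstream of the TSS
(strand-aware; the downstream extent is capped at the transcript span for
transcripts under 1 kb; regions truncate at chromosome ends with a flag).
For multi-transcript loci the canonical — longest spliced — transcript's
TSS is used.

Scores are log2 log-odds against a zero-order background (pseudocount
1e-4 on probabilities). P-values are **exact**: scores are integerized at a
precision of 1/1000 bit and the full score distribution under the
background is built by dynamic programming (column-by-column convolution);
the survival function at the observed score is the p-value. The DP equals
full 4^w enumeration at the same integerization, verified up to w = 8. Both
strands are scanned; the reverse-complement matrix is scored under the same
sequence-side background, and scanning the reverse complement of a sequence
mirrors offsets and swaps strands with identical scores.

Multiple testing is BH over **all (motif, window) tests of a run** (scope is
configurable), retaining q < 0.05. A consequence worth knowing: a PWM's
smallest attainable p-value is 4^−w under a uniform background, so short
motifs (w ≲ 9) cannot clear a run-wide BH cut across ~10^5 windows no
matter how perfect the match; the planted-recall conditions therefore use
width-12 near-deterministic PWMs. The per-TF presence matrix marks a region
when any of the TF's motifs has a retained hit; TFs present in more than
100 regions are highlighted (parameter, study default). TF–lncRNA
regulation candidates require |r| > 0.75 and p < 0.01 on expression.

## Lift-over and SNP intersection

UCSC chain files are parsed with per-chain validation of block arithmetic
against the header spans. An interval maps base-by-base through the aligned
blocks of the best-scoring overlapping chain; the result spans the mapped
bases on the target (negative-strand chains reflected into plus
coordinates). A query is unmapped when its mapped-base fraction falls below
`min_match` (default 0.1, the usual cross-species setting) or when it
straddles chains without any single chain covering it ("split" — the
conservative behavior). SNP positions are 1-based in the table and
converted to 0-based points; a SNP at the very start of a mapped half-open
interval is inside.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed).

- **Annotation**: one isolated cassette per planted lncRNA (60 kb spacing)
  containing a 3-exon PCG and a lncRNA constructed to satisfy exactly one
  class and no higher-precedence one; two-exon fraction (default 0.4) and
  length ranges are controllable. An audit in the test suite re-derives each
  planted class from the emitted models before other tests rely on them.
- **Counts**: the 4-group, n = 3 design; baseline expression lognormal in
  log2 (defaults: mean 6, sd 1.5; recovery conditions use μ = 100, sd 0),
  library-size factors uniform in [0.7, 1.4], NB sampling via gamma–Poisson
  with variance μ + αμ² (α = 0 ⇒ Poisson). DE genes follow one of five
  temporal archetypes (gradual down; late up; gradual up; early transient;
  early sustained) scaled to a peak fold-change, or a flat two-group shift
  for recovery tests. FPKM derives from counts with planted transcript
  lengths. Planted co-expressed pairs share a fold profile, making both
  members DE and positively correlated.
- **Co-expression**: planted groups share a standardized latent profile
  plus N(0, σ²) noise, so the expected pairwise Pearson r is 1/(1 + σ²) —
  recorded in the truth object.
- **Promoters**: i.i.d. background sequence with motif occurrences sampled
  base-by-base from PWM columns at recorded offsets and strands.
- **Chain/SNPs**: a piecewise chain (5 kb blocks, 100 bp source gaps), its
  exact inverse for round-trip checks, and SNPs planted inside/outside the
  images of the source intervals.

What passing these tests shows: the algorithms are implemented correctly
(oracle equivalence), calibrated under their own model (null rates), and
powerful under the stated planted conditions. What it does not show:
robustness to features real data have and the generators omit — GC and
length biases, correlated gene networks beyond the planted groups, batch
effects (the design carries a batch column but no batch signal), partial
annotation, higher-order sequence composition, and multi-chain alignment
ambiguity.

## Problem sizes in routine runs

The default end-to-end configuration uses 600 genes (60 lncRNA) × 12
samples, 6 lncRNAs per class (48 cassettes), 200 GSEA permutations, 40
promoter regions of 400 bp and 3 PWMs, chosen so a full run takes seconds
and the complete verification suite stays well under a minute of compute;
all sizes are parameters of `PipelineConfig`, and the statistical
components scale linearly in genes × samples (the exact test additionally
in the pooled count per gene).
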