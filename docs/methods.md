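# Methods

## Coordinate and format conventions

All internal coordinates are 0-based half-open; the only conversion happens
at the GTF boundary (1-based inclusive on disk).  The TSS is the strand-
dependent transcript 5' end: `tx_start` for plus-strand genes, `tx_end − 1`
for minus-strand genes.  BED3+/BED6 and bedGraph follow the UCSC
definitions; GTF follows the GENCODE dialect (gene/exon features with
`gene_id`/`gene_name` attributes, optional UTR features); PWMs use a
minimal MEME-motif text dialect; gene sets use GMT.

## Dual-probe consensus

Peak sets from the two independent probe pulldowns are intersected per
chromosome; the output is the union of all pairwise intersections with
overlapping retained segments merged, so every output base is supported by
at least one peak from each probe set.  The minimum accepted overlap is
1 bp — the intersection rule retains any overlapping region, without a
width threshold.  When incoming peak records carry a q column it is applied
(q < `peak_q`, default 0.05) *before* intersecting; re-filtering after the
intersection is not done.

## Peak-to-gene annotation

A peak is assigned to the gene minimizing |peak midpoint − TSS| on its
chromosome (equidistant ties break to the lexicographically smaller gene
id).  Feature classification uses the peak midpoint with precedence
promoter > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic;
"promoter" means |signed TSS distance| ≤ `tss_window_bp` (default 3000) and
"downstream" means within the same distance past the annotated gene end on
the gene's strand — the promoter half-width mirrored, since no separate
convention is established for it.  Midpoint classification (rather than
full peak extent) keeps multi-feature overlaps deterministic and testable.

## Differential expression

The engine is a transparent method-of-moments negative-binomial Wald test
rather than a shrinkage estimator: the cascade consumes only the
significance call at FDR 0.1 plus the fold-change sign, and a transparent
test makes its calibration directly testable.

* Size factors: median over all-positive genes of `count / geometric mean`,
  rescaled to geometric mean 1; falls back to total-count ratios (with a
  warning) when no gene is positive everywhere.
* Low-count filter: genes with total raw count < `low_count_min_total`
  (default 10) are excluded before testing.
* Dispersion: per gene, `α̂ = max((s² − μ̂)/μ̂², 1e−8)` computed within each
  condition and pooled by degrees of freedom.
* Statistic: `log2FC / SE` with the delta-method SE given in the README,
  pseudo-count 0.5 on normalized group means for finiteness at zero.
* Reference distribution: Student t with `n₁ + n₂ − 2` degrees of freedom.
  With 3 vs 3 replicates the moment dispersion estimate carries only ~4 df
  of information; a normal reference is markedly anticonservative there
  (empirically ~0.12 type-I error at nominal 0.05), while the t reference
  keeps the all-null rejection rate at ~0.05.  This choice is verified by
  the calibration test (2000 null genes, 3 vs 3, dispersion 0.05: fraction
  of p < 0.05 required within [0.03, 0.07]).
* Multiple testing: Benjamini–Hochberg step-up; `direction` is up/down only
  when `padj < de_fdr`.

The NanoString-style panel path normalizes first on positive technical
controls (per-sample geometric-mean factor), then on the `k = 3`
housekeeping candidates with the lowest coefficient of variation (k is
configurable; the count is not externally standardized), and tests DM vs
CTRL fold changes with a two-tailed unpaired Student t.

## Motif scanning

Scores are log-odds in bits against the background after adding pseudocount
0.01 to PWM probabilities (avoids −∞; standard practice).  The background
is uniform by default — exactly the null of the synthetic genome — and can
be supplied.  P-values are exact: scores are discretized at 1e−3 bits and
the full null score distribution is computed by dynamic programming; the
scanner computes k-mer scores on the same integer grid, so a scanned score
maps to its exact tail probability.  Every position on both strands of
every window is scored; q-values are BH across all scored positions *per
PWM* (the default multiple-testing universe of standard occurrence
scanners), and hits are retained at q < `motif_q` (default 0.05).  Promoter
windows cover [TSS − 1500, TSS + 500) in transcription orientation;
windows truncated at a chromosome end are padded with N (which scores 0)
and flagged.  Per-hit significance is used throughout; no promoter-level
aggregation statistic is defined, so none is applied.

## Target classes, coherence, network, common core

A gene is *bound* when ≥ 1 consensus peak is assigned to it, regardless of
feature class — nearest-gene assignment places true regulatory binding in
gene bodies and distal elements, not only promoters.  Classes: RDG = DEG
and bound; RIG = DEG and not bound; bound-only; unchanged.  These partition
the union of genes seen in either input, and |DEG| = |RDG| + |RIG| holds by
construction.

Coherence across cell models requires only an equal fold-change sign; the
magnitude is deliberately not thresholded.  The network universe is the set
of genes deregulated in *both* models; an edge TF → gene exists iff the TF
is a coherent direct-target TF with a PWM, the gene is in the universe, and
at least one retained hit lies in the gene's promoter window.  TFs lacking
a PWM are listed in a side table rather than silently dropped.  The common
direct-target core intersects four collections — lncRNA-bound direct
targets and TF ChIP targets in the discovery model, and the two knockdown
DEG lists in the second model — with per-gene provenance flags; any
assigned peak qualifies a gene as "direct" (promoter-proximal binding is
not required, matching known cases of enhancer-mediated direct targets).

Pairwise Spearman correlations use average ranks for ties and the
two-sided t approximation `t = R√((n−2)/(1−R²))` with n−2 df; constant
genes yield flagged NaN correlations.

## Enrichment and term clustering

Over-representation uses the upper hypergeometric tail with BH across all
tested terms at α = 0.05.  The universe is the intersection of the supplied
background with the expression-tested genes (the tool-default background of
panel software varies and is not standardized; making it explicit keeps
term totals reproducible *within* this package only).  Term similarity is
Jaccard on member genes; clustering uses deterministic greedy modularity
maximization over the graph with edges at similarity ≥ 0.2 (`edge_min`,
configurable; no standard value exists).  Greedy modularity replaces
order/seed-sensitive Louvain so partitions are reproducible run to run; on
small graphs it attains the exhaustively verified optimum in the suite.

## Synthetic study design

The generator plants a two-layer cascade and emits every file the pipeline
consumes.  Defaults (the study conditions):

| parameter | default | note |
| --- | --- | --- |
| genome | 2 chromosomes × 1 Mb, i.i.d. uniform ACGT | uniform background makes exact scan p-values correct by construction |
| genes | 300, non-overlapping, 1–3 exons, gaps ≥ 3.6 kb | generous gaps keep nearest-TSS assignment unambiguous |
| TF catalog | 20 TFs + 12 co-factors | |
| direct targets | 60 (8 TFs, 4 co-factors) | planted |log2FC| ∈ [0.8, 2]; TFs [1.8, 2.2] |
| downstream genes per TF | 5–30, ~30% drawn from direct targets | effect sign = TF sign, |log2FC| ∈ [0.8, 2] |
| binding sites | 6 per TF locus, 2 per other direct target, 1 per bound-only gene (15), width 200–380 bp within ±1.4 kb of the TSS | TF loci as dense binding hubs |
| counts | NB, dispersion ∈ [0.01, 0.05], baselines log-uniform [100, 2000] (TFs [800, 2000]), 3 vs 3, library factors [0.8, 1.25] | cell-line-grade dispersion |
| peaks | detect_prob 0.9 per probe set, ±50 bp jitter, 2 noise peaks/Mb | |
| motifs | length 12, consensus probability 0.85 (~14 bits) | |
| partner TF | first planted TF; 25 + 20 ChIP targets, its own model-B knockdown matrix | feeds the common-core derivation |

Ten genes are simulated at near-zero expression to exercise the low-count
filter; they are excluded from all target sets.  All randomness flows from
the single config seed through named per-module substreams, so runs are
byte-reproducible and individual stages can be re-generated.

What the generator does **not** emulate: GC/mappability biases, overlapping
or nested genes, realistic exon/intron size distributions, correlated
dispersion–mean trends, batch effects, positional binding preferences
beyond TSS proximity, and motif co-occurrence structure.  Passing recovery
tests therefore demonstrate the correctness and calibration of the cascade
under its stated model, not performance on real sequencing data.

## Problem sizes used in validation

The recovery suite runs the full cascade on generator defaults across 20
seeds (~160 planted sites, 60 direct targets, 8 planted TFs per seed); the
reproduction script uses 10 seeds plus dedicated calibration simulations
(2000 null genes for type-I error; 200 genes at planted log2FC = 2).  These
sizes give binomial standard errors small enough for the stated bands while
keeping a full validation run in the tens of seconds.

## Known limitations

* The moment-based dispersion estimate is noisy at 2–3 replicates; the t
  reference compensates on average but individual gene SEs remain rough —
  no shrinkage across genes is applied.
* Exact scan p-values assume an i.i.d. background; on real promoters
  (CpG islands, repeats) they are optimistic.
* The edge evidence is motif occurrence, not binding; edges are putative
  regulatory relations.
* Network edge recall is reported relative to planted TF–gene pairs whose
  target reaches the common-DEG universe and whose TF passes the coherence
  filter: at 3 vs 3 replicates a planted |log2FC| of 0.8 is detected in
  both models only ~83% of the time, which bounds recall against *all*
  planted pairs by detection power rather than by the scanning or network
  logic the metric is meant to probe.
* `cluster_terms` is greedy; on large dense similarity graphs it may
  return a locally optimal partition.
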