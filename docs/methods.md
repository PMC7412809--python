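# Methods

## The regulatory-potential model

The model assumes the effect of an accessible element on a gene's
transcription is independent across elements, additive, and decays
exponentially with genomic distance. For peak *i* and gene *j* at
distance *d_ij* (peak center to strand-aware TSS),

    W_ij = 2^(−d_ij / d0),

so `d0` is the distance at which influence halves. Defaults: `d0 =
10,000 bp` (enhancer-driven regulation; a 1 kb preset suits
promoter-driven analyses) and a hard truncation `distance_cutoff =
150,000 bp`. At the cutoff the weight is 2⁻¹⁵ ≈ 3.05 × 10⁻⁵ < 5 × 10⁻⁴,
so truncation discards at most 5 × 10⁻⁴ per peak-gene pair while keeping
W sparse. Gene activity is the exact sparse product R = WᵀB over the
binarized peak-by-cell matrix; no further normalization is applied at
this stage.

The default **enhanced** model adds two rules, evaluated per (peak,
gene) in precedence order:

1. *Own-exon rule.* A peak overlapping any exon of gene *j* scores as if
   it sat on the TSS (weight 1) and is then normalized by the gene's
   total merged exon length: `W_ij = exon_length_scale /
   total_exon_length`. The published formulation gives the reciprocal
   without a unit; we expose `exon_length_scale` (default 1000, i.e.
   per-kilobase) so exon contributions sit on the same order as proximal
   decay weights; `scale=1` recovers the raw reciprocal. Exonic
   accessibility tracks Pol II engagement on actively transcribed genes,
   which is why these peaks are pulled to the TSS rather than decayed.
2. *Other-gene exclusion.* A peak lying in the promoter window
   (TSS ± `promoter_flank`, default 2000 bp) or an exon of any *other*
   gene contributes 0 to gene *j*: without this rule the promoter of a
   highly expressed neighbor inflates the score of every gene within the
   decay window. A gene's own promoter never blocks it, and the own-exon
   rule takes precedence, so a peak in an exon shared by overlapping
   genes scores for each gene whose exon it touches.

Distance is measured from the peak *center*; exon and promoter overlap
use any-base overlap of the full peak interval. One TSS per gene (the
annotated strand-aware gene start) is used; alternative isoform TSSs are
out of scope. "Nearby" in the exclusion rule means any other gene whose
promoter or exon the peak overlaps, with no distance limit — the
simplest reading, and the only one that needs no extra parameter.

## Quality control

RNA barcodes pass when reads > 1000 (strict), detected genes ≥ 500,
mitochondrial fraction ≤ 5%, and spike-in fraction ≤ 5%. ATAC barcodes
pass when reads > 1000, the count-weighted fraction of fragments
overlapping any promoter window is ≥ 10%, and the mitochondrial
fraction is ≤ 10%. Strictness follows the wording the thresholds were
stated with ("more than" strict, "at least"/"no more than" non-strict).
The promoter fraction deliberately replaces a fraction-of-reads-in-peaks
filter: aggregate peak calls are dominated by major populations, and a
FRiP cutoff can silently discard rare cell types. Peak matrices are
binarized (entry > 0 → 1) before any ATAC analysis, reflecting the
essentially binary accessibility of a diploid genome.

## Normalization, features, embedding, clustering

Expression is scaled to 10,000 counts per cell and log1p-transformed;
binary peak matrices are depth-weighted by each cell's open-peak count.
Variable-gene selection fits a polynomial mean-variance trend in log10
space, standardizes each gene by its expected standard deviation, clips
z-scores at √n_cells, and ranks genes by the variance of the clipped
values (top 2000 by default). The ATAC embedding is TF-IDF — term
frequency = entry over column sum, IDF = ln(1 + n_cells / peak
occurrence) — followed by rank-50 truncated SVD; cell coordinates are
the right singular vectors scaled by the singular values. The TF-IDF
dialect is one of several in circulation; it is fixed here and
documented rather than configurable per sub-formula.

Clustering builds a kNN graph (default 20 neighbors) on the embedding,
re-weights edges by the Jaccard similarity of the endpoint
neighborhoods, and optimizes modularity at resolution 0.6 with the
Leiden algorithm (seed 2020, required for determinism). Leiden was
chosen over classic Louvain as the stronger optimizer of the same
resolution-parameterized objective. Note that modularity optimization on
low-dimensional geometric graphs tends to subdivide large diffuse
groups; the intended operating regime is embeddings of dimension ≥ 5,
where well-separated populations are recovered exactly.

## Differential analysis

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests. When the
group split is small enough to enumerate (≤ 20,000 splits) the p-value
is an exact permutation enumeration; otherwise the tie-corrected normal
approximation is used. logFC = ln((mean_in + 1)/(mean_out + 1)) on
de-logged normalized values — natural log with pseudocount 1, the
convention of the fast rank-sum marker frameworks. Reported markers
satisfy logFC > 0.25, presence ≥ 0.25, p < 1e−5 for genes and 0.1 /
0.01 / 1e−5 for peaks. Raw p-values are used with these fixed cutoffs;
no multiple-testing correction is applied because the thresholds are
defined on raw p. Clusters with fewer than 3 cells are skipped with a
warning.

## Cell-type annotation

For each cluster, every gene's logFC versus all other cells is computed
(no significance filter; signs are kept). A signature's score is the sum
of its present markers' logFC divided by log2(max(2, n_present)); the
max(2,·) guard keeps singleton signatures finite, and only markers
present in the matrix enter both numerator and denominator. The
highest-scoring signature names the cluster (ties break
lexicographically); if no signature scores strictly above 0 the cluster
is "others", flagging possible unknown populations. ATAC clusters are
annotated identically after log-normalizing the gene activity matrix.

## Regulator inference

Enrichment of a regulator's reference peak set in a cluster's specific
peaks is a one-sided Fisher exact test on the 2×2 table over the peak
universe (in-cluster × overlaps-reference; each query peak counts once).
The composite score is −log10(p) × log2(OR) with Haldane +0.5 smoothing
on the odds ratio so it is defined with zero cells; the p-value is
computed on the raw integer table (a smoothed table has no exact Fisher
p). The reported p is always the enrichment tail, but the score's
magnitude uses the tail matching the direction of effect, so depleted
sets carry a negative score rather than collapsing to zero. A regulator
with several reference sets keeps only its best-scoring one, and output
tables truncate to the top 100 regulators per cluster.

PWM similarity is the information-content-weighted mean Pearson
correlation of aligned columns, maximized over all alignment offsets
with at least 5 overlapping columns and over the reverse complement;
IC = 2 + Σ p·log2 p per column, and a zero-variance (uniform) column
contributes correlation 0 (its IC weight is 0 anyway). Families come
from average-linkage hierarchical clustering on 1 − similarity, cut at
similarity 0.7. Every family member inherits the family's best
enrichment score — regulators of one family share binding motifs, so
reference-set enrichment cannot distinguish them and expression must
arbitrate: survivors are re-ranked by mean expression (RNA context) or
mean RP (ATAC context), and regulators with zero mean expression or
mean RP < 0.5 are dropped. Rankings from the two modalities combine by
the rank product √(r_RNA × r_ATAC), with a missing regulator assigned
that modality's worst rank plus one.

## Integration and label transfer

Shared-gene expression and gene-activity matrices are standardized per
gene within each modality; the rank-k SVD (default k = 20) of XᵀY
places RNA cells on the left singular vectors and ATAC cells on the
right, each row L2-normalized. Anchors are mutual nearest neighbors
across modalities (default k_anchor = 5), weighted by 1 minus the pair's
mean rank fraction in the two neighbor lists. Each ATAC cell's label
distribution is the normalized Gaussian-kernel vote of its k_weight = 20
nearest anchors (bandwidth = the neighborhood's largest distance,
multiplied by the anchor weight); the argmax is the prediction and its
share the prediction score, with > 0.5 the high-quality convention.
This is a deliberate simplification of the full anchor-filtering and
quantile-trimming machinery of the large integration frameworks: the
scientific content here is the RP input to integration, not the transfer
algorithm, and the TransferResult schema accepts externally computed
transfers for comparison.

## Evaluation statistics

NMI uses arithmetic-mean normalization of the mutual information
(natural logs). Gini of a nonnegative vector is Σ_ij |x_i − x_j| /
(2 n Σx), computed by the sorted O(n log n) identity and checked against
the double loop in tests; RAGI is the mean Gini of marker genes'
per-cluster mean activity minus the same for housekeeping genes, so it
is antisymmetric in its two gene sets. Median F1 is the median over true
classes of 2PR/(P+R) with zero-division mapped to 0. The
expression-activity consistency statistic is the per-cell-type Spearman
correlation between mean expression (RNA cells of the type) and mean
activity (ATAC cells of the type) over a gene subset.

## The synthetic benchmark

`synthetic_fixtures` generates one artificial chromosome with
non-overlapping genes (8 kb bodies, two exons, 60 kb spacing), one
promoter peak centered on each TSS, one exonic peak, 1–3 distal peaks
within the decay cutoff, and background peaks beyond 150 kb of every
TSS. Default study conditions: 4 cell types, 100 cells per type per
modality, 150 genes, 2000 peaks, 20 marker genes per type, baseline
open probability 0.25 (0.8 for promoters), marker effect size 4 (open
probabilities multiplied by 4, capped at 0.95), mean RNA depth 5000,
negative-binomial dispersion 0.2 — the canonical overdispersed scRNA
noise model. RNA means are proportional to the enhanced-model RP of the
cell type's expected open-peak profile, so the expression–accessibility
coupling the RP model assumes is planted by construction. A
`cell_depth_factor` scales all open probabilities to emulate
sequencing-depth titration. The fragment generator emits 1–3 fragments
per open peak per cell and appends planted bad barcodes that each
violate exactly one ATAC QC threshold (≈300 reads; zero promoter
fragments; ≈30% mitochondrial reads).

What the fixture does *not* emulate: realistic peak-width and GC
structure, doublets, batch effects, ambient contamination, overlapping
or nested genes, and chromatin-expression decoupling (e.g. primed but
inactive enhancers). Passing the recovery tests therefore shows the
pipeline is correct and well-calibrated under its own model assumptions,
not that it is robust to every artifact of real data.

## Numerical and design notes

- All internal coordinates are 0-based half-open; GTF input is shifted
  on read. Matrices travel as MatrixMarket triplets with `.rows`/`.cols`
  sidecar name files (dense TSV accepted for toys).
- All-zero cells stay all-zero through every normalization; Gini of an
  all-zero vector is defined as 0.
- Truncated SVD uses a seeded start vector; community detection takes an
  explicit seed (default 2020); the fixture generator derives all
  sub-seeds from its single seed, so reruns are byte-identical.
- Ties break lexicographically everywhere a ranking is reported
  (annotation argmax, enrichment ranks, rank products).
- Benchmark problem sizes (400 cells per modality, 2000 peaks, 150
  genes) were chosen as the smallest at which the planted structure is
  comfortably identifiable; they keep the full test suite and the
  acceptance script to well under a minute each.

## Known limitations

- RNA-side regulator inference reuses the same generic peak-set
  enrichment on user-supplied reference sets rather than a full
  epigenetic-landscape model of the kind dedicated published systems
  provide; externally produced enrichment tables can be slotted in
  through the EnrichmentRecord TSV schema.
- Variable-gene selection densifies the matrix; it is intended for
  desk-scale gene counts, not 10⁶-cell atlases.
- The PWM similarity kernel is a documented, deterministic
  reimplementation of the IC-weighted-correlation idea, validated
  against its own exhaustive-offset oracle rather than against any
  specific external motif-clustering tool.
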