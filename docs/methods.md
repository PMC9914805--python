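# Methods

`lenscape` re-implements, as a reusable and fully tested library, the
integration analysis that links chromatin accessibility (ATAC-seq) to gene
expression (RNA-seq) in cultured lens epithelial explants. The study design
it targets has six conditions — immediate collection (IMD), 24 h in culture
medium (D0), and one or five further days in plain culture medium (D1_CM,
D5_CM) or 50%-vitreous "differentiation medium" (D1_DM, D5_DM) — with three
RNA replicates and two ATAC replicates per condition. All statistics operate
on plain count matrices and interval annotations, so the same code runs on
real data (GTF, BED/narrowPeak, TSV counts, JASPAR PFMs) or on the built-in
synthetic generator.

## Normalization and differential calling

Samples are made comparable by median-of-ratios size factors: for each
sample, the median over reference features (features with all-positive
counts) of the ratio between the sample's count and the feature's geometric
mean across samples. This estimator assumes a majority of features are not
differential; the synthetic generator honors that assumption (see below).

The differential test is an explicit stand-in, not a negative-binomial GLM:
log2 fold change is computed from pseudo-counted group means of normalized
counts (`lfc = log2((mean_b + 0.5)/(mean_a + 0.5))`), the p-value from a
Welch t-test on `log2(normalized + 1)`, and adjustment by Benjamini–Hochberg
within each pairwise comparison. Externally computed differential tables can
be injected through `read_diff_table`, and everything downstream consumes
only the `(feature, lfc, pvalue, padj)` contract. Two design notes:

* **Thresholds are inclusive**: a feature is differential iff
  `|lfc| >= 1.5` and `padj <= 0.05`. The fold-change criterion is applied to
  the absolute value, so down-regulated features are captured.
* **Variance moderation (optional).** A Welch t with two replicates per
  group has ≈2 degrees of freedom and, after FDR adjustment, essentially no
  power. For the two-replicate accessibility design
  `differential_standin(..., moderated=True)` shrinks each feature's pooled
  variance toward the median variance across features (prior weight of 4
  pseudo-observations) and adds the prior degrees of freedom to the t
  reference distribution. The default remains the plain Welch test.

The non-redundant DEG/DAR set is the union of significant features over the
fifteen pairwise comparisons of the six-condition design (every unordered
pair).

## Archetype clustering

Features in the non-redundant set are row z-scored (mean 0, SD 1 across
samples) so that cluster shapes — not magnitudes — drive the partition, then
clustered with K-means using the Hartigan–Wong update rule: after a Lloyd
pass, points are transferred one at a time whenever moving point *x* from
cluster *c* to *d* reduces total within-cluster sum of squares, using the
exact costs `n_c/(n_c-1)·d(x,µ_c)²` and `n_d/(n_d+1)·d(x,µ_d)²`. The best of
25 random initializations by inertia is kept; runs that produce an empty
cluster are re-initialized. `k = 6` by default for both modalities; no model
selection for k is attempted. Replicates are kept as separate columns
(clustering on per-sample normalized counts); per-condition means are
available as an option through `condition_means`.

## Peak annotation

Each peak is reduced to one anchor — the summit when available, otherwise
the interval midpoint — and assigned exactly one of eleven categories:
three promoter distance bins (≤1 kb, 1–2 kb, 2–3 kb from the nearest TSS,
symmetric in distance), 5' UTR, 3' UTR, first exon, other exon, first
intron, other intron, downstream (within 300 kb past a gene's 3' end in gene
orientation), and distal intergenic. TSS distance is signed in gene
orientation (negative = upstream); nearest-gene ties break to the
lexicographically smaller gene id. When an anchor satisfies several genic
definitions the precedence ladder is promoter > UTR5 > UTR3 > FirstExon >
OtherExon > FirstIntron > OtherIntron > Downstream > DistalIntergenic,
mirroring the default priority of the common nearest-TSS annotators.

Two open choices are worth flagging. The downstream window defaults to
300 kb, following the category definition used in the analysis this package
reproduces, although many annotation tools default to 300 bp; it is a
parameter. And the TSS is gene-level (union transcript span), not
per-transcript; transcript-level TSS sets would shift promoter-bin
assignments for genes with distant alternative starts.

## Integration statistics

**Peak-to-gene matching** uses the nearest-promoter gene from the annotation
records; genes with several matched peaks get the arithmetic mean of their
peaks' normalized counts. For correlation analyses, restricting the matching
to promoter-category peaks isolates promoter accessibility, which is the
quantity the per-gene correlation categories describe.

**Correlation.** Because the replicate designs differ (3 RNA vs 2 ATAC),
samples are paired at the condition level using per-condition replicate
means. Correlations are computed on `log2(x + 1)` of normalized counts by
default (`log2=False` reverts to the raw scale): counts are approximately
log-normal, and the log scale is where a latent log2-scale association is
linear. The global r pools all (gene, condition) pairs; per-gene r is
computed across the six condition means and binned as strong (|r| ≥ 0.9),
moderate (0.5 ≤ |r| < 0.9), or none (|r| < 0.5) — configurable thresholds,
since the original analysis reports category counts but not cutoffs. A gene
with zero variance in either assay has undefined r and category `none`.

**Cluster association.** The RNA-cluster × ATAC-cluster cross-table counts
genes by joint membership (a gene's ATAC cluster is that of its nearest
peak; a majority rule is available). Independence is tested globally with a
Pearson chi-squared test, and per cell with a fixed-margin permutation test:
one label vector is uniformly permuted (distributionally identical to
permuting both — only the relative alignment matters), the table is
recomputed per permutation, and a cell's empirical p is the fraction of
permutations whose count reaches the observed count. A cell is *associated*
when fewer than 5% of permuted counts do so; no multiple-testing correction
is applied across cells, matching the published per-cell criterion. Under
this scheme each cell's null is exactly hypergeometric, which the test suite
uses as a closed-form oracle.

**Direction concordance** tallies every mapped peak by its own
differential-accessibility direction and its nearest gene's expression
direction for a CM-vs-DM comparison (3×3: up-in-first / no difference /
up-in-second). The unit is the peak, so grand totals equal the number of
mapped peaks.

**Fisher direction test.** Two-sided Fisher exact test on a 2×2 of
(gene set) × (regulation direction) counts, e.g. epithelial-identity vs
fiber-identity genes by down/up status.

**TSS quintile profiles.** Genes are ranked by mean expression within each
condition (stable sort, ties broken by gene id), split into five equal-size
bins (remainder to the lowest-expression bins; quintile 1 = highest), and
the replicate-mean ATAC coverage in 10 bp bins across ±2 kb of the TSS
(strand-flipped so upstream is left) is averaged per quintile.

## Binned motif enrichment

Sequences are scanned with position probability matrices (JASPAR counts plus
a 0.5 pseudocount per cell, column-normalized) by log2-odds scoring against
the motif background; a window is a hit when its score reaches 80% of the
maximum attainable score, both strands are scanned, and `N` bases contribute
zero log-odds. Regions are stratified by LFC: a center bin holds the
non-differential zone (|LFC| < 1.5) and each side is split into equal-count
bins by rank. Each (motif, bin) pair is tested for over-representation
against all other bins with an upper-tail hypergeometric test —
a deliberate simplification of randomized/binomial binned-enrichment
machinery, validated by null calibration (unplanted motifs cross the cutoff
in <1% of pairs) rather than by tool equivalence. Significance uses the
stringent p < 5×10⁻⁵ cutoff. Per-bin GC content is reported but not
corrected for. Promoter vs non-promoter analyses are obtained by filtering
the region set on annotation categories before binning
(`filter_regions_by_category`).

## The synthetic generator

`simulate` produces a deterministic function of `(config, seed)`:

* **Annotation**: genes packed on a toy genome with ≥6 kb inter-gene flanks,
  random strands, 1–4 exons (alternating exon/intron chunks ≥100 bp), and
  UTRs carved from the terminal exons. Default scale: 2,000 genes and 6,000
  peaks on one 20 Mb chromosome.
* **Counts**: each feature's latent log2 profile over the six conditions is
  baseline + cluster archetype + jitter. Six default archetypes (2.0 log2
  units, mean-centered) loosely mimic the published cluster shapes
  (IMD-high, vitreous-responsive, culture-time-responsive, ...). Counts are
  Gamma–Poisson (negative binomial) around `depth_factor × 2^latent` with a
  single shared dispersion (default 0.05); at dispersion 0 the rounded means
  are returned deterministically, giving exact limit-case tests.
* **Null features**: a fraction `frac_null` (default 0.55) of genes and
  peaks have no condition effect (cluster label 0). This is not cosmetic:
  median-of-ratios normalization is only identifiable when a majority of
  features are non-differential, exactly as in real data. With no null
  majority, condition-level signal leaks into the size factors and biases
  every downstream condition mean.
* **Peaks**: one promoter peak per gene with its summit within 1 kb of the
  TSS, plus distal distractor peaks kept ≥3.5 kb from every TSS so that
  promoter-bin categories contain exactly the planted promoter peaks.
* **Association**: a gene's promoter-peak cluster is sampled conditionally
  on its RNA cluster with configurable odds (default: odds 5 on one pair,
  emulating the strongest published cluster association).
* **Correlation**: the planted expression↔promoter-accessibility
  correlation ρ is realized *exactly* at the latent level by a per-gene
  Gram–Schmidt construction — the peak's centered condition profile is
  `ρ·x̂ + √(1−ρ²)·ŷ⊥`, where `x̂` is the gene's standardized profile and
  `ŷ⊥` the ATAC component orthogonalized against it — with gene and peak
  baselines linked the same way so the pooled (global) correlation also
  approaches ρ. Count noise attenuates the realized r mildly (≈0.55 at
  ρ = 0.6 under default noise).
* **Coverage**: per-sample TSS profiles are Gaussian bumps centered on the
  TSS bin whose amplitude is the gene's condition-mean expression, times
  multiplicative noise — so quintile ordering is monotone by construction.
* **Sequences**: i.i.d. uniform A/C/G/T backgrounds with exact consensus
  motif instances planted per (motif, bin) at configured frequencies, on a
  uniformly chosen strand.

What the generator does *not* emulate: per-feature dispersion, GC or
fragment-length biases, batch effects, read-level artifacts, or correlated
peaks beyond the one-promoter-peak-per-gene link. Passing recovery tests on
this surface therefore demonstrates the correctness of the pipeline's
logic and statistics, not robustness to every real-data pathology.

## Numerical and degenerate-input choices

* BH adjustment is the standard step-up procedure with monotonicity
  enforcement; input order is preserved.
* Zero-variance feature rows are dropped (with a warning) before z-scoring
  and clustering; zero-variance correlation vectors give r = NaN and
  category `none`; a fold ratio with a zero numerator day is reported as
  undefined rather than infinite.
* Empty K-means clusters trigger re-initialization of that run; inertia is
  non-increasing across Hartigan–Wong sweeps by construction.
* Permutations, K-means and all generators consume a single integer seed
  through `numpy.random.default_rng`; results are bit-reproducible.
* Problem sizes in the test suite (hundreds of genes, a few thousand
  permutations) are chosen so the full suite runs in a few minutes on one
  CPU; the acceptance checks that mirror published quantities use the
  published sizes (N = 7,193 label permutations × 100,000).

## Known limitations

* The stand-in differential test is not a negative-binomial GLM; with few
  replicates its unmoderated form is conservative. Real differential tables
  can be supplied instead.
* Gene-level TSS and nearest-promoter matching ignore alternative
  transcription starts and enhancer-to-gene links beyond proximity.
* The binned motif test ignores GC composition differences between bins
  (GC is reported so users can judge).
* The global correlation depends on between-gene magnitude structure; it is
  not comparable across datasets with different expression ranges (the
  per-gene categories are the scale-free summary).
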