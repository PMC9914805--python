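# lenscape

Integration of chromatin accessibility (ATAC-seq) and gene expression
(RNA-seq) for six-condition lens epithelial explant experiments — and, more
generally, for any paired count-matrix design over a small set of
conditions.

Lens epithelial explants cultured with vitreous humor undergo chromatin and
transcriptome remodeling toward a fiber-cell-like state. Analyzing that
process requires linking two assays: differentially accessible regions
(DARs) and differentially expressed genes (DEGs) are called across all
fifteen pairwise comparisons of the conditions (IMD, D0, D1_CM, D1_DM,
D5_CM, D5_DM), clustered into archetypes, and compared through peak-to-gene
matching. `lenscape` implements that pipeline as a library:

* **io** — GTF gene models, BED/narrowPeak peaks, JASPAR PFMs, TSV count
  matrices with condition metadata (explicit 0-based/1-based conventions).
* **differential** — median-of-ratios size factors; a documented stand-in
  differential test (log2 fold change from pseudo-counted means, Welch t on
  log2 counts, Benjamini–Hochberg within comparison; optional variance
  moderation for 2-replicate designs); the inclusive |LFC| ≥ 1.5,
  padj ≤ 0.05 filter; the non-redundant union over the 15 comparisons.
* **cluster** — Hartigan–Wong K-means on row-z-scored profiles (k = 6 by
  default), with per-cluster condition profiles.
* **annotate** — the eleven-category genomic annotation (promoter bins ≤1,
  1–2, 2–3 kb; UTRs; first/other exon; first/other intron; ≤300 kb
  downstream; distal intergenic), signed TSS distances, promoter vs
  non-promoter DAR summaries with fold ratios.
* **integrate** — nearest-promoter peak-to-gene matching; global and
  per-gene expression↔accessibility Pearson correlation with strength
  categories; the cluster cross-table with chi-squared and a fixed-margin
  permutation association test (a cell is associated when fewer than 5% of
  100,000 permuted counts reach the observed count); direction-concordance
  tables; the two-sided Fisher direction test; TSS metaprofiles by
  expression quintile.
* **motifs** — log2-odds PWM scanning (both strands, 80%-of-max hit
  threshold), LFC binning around a |LFC| < 1.5 center bin, and upper-tail
  hypergeometric per-(motif, bin) enrichment at p < 5×10⁻⁵.
* **simulate** — a synthetic-data generator that emulates the study design
  with planted archetypes, cluster associations, expression↔promoter
  correlations, TSS coverage, and motif instances, with full ground truth
  for recovery testing.

The statistical core, in the field's notation: for clusters with fixed
sizes, the per-cell permutation null of the cross-table count n_ij is
hypergeometric with parameters (N, n_i·, n·j); a cell is *associated* when
`#{permutations with count ≥ n_ij} / 100,000 < 0.05`. Per-gene correlation
is Pearson r across the six condition means of `log2(normalized counts + 1)`,
categorized at |r| ≥ 0.9 (strong) and 0.5 (moderate).

## Worked example

`examples/04_integrate.py` simulates a 500-gene / 1,500-peak dataset with a
planted expression↔promoter-accessibility correlation of 0.6, runs the full
pipeline, and prints:

```
global expression<->promoter-accessibility Pearson r = 0.543 (planted 0.6)
per-gene correlation categories: {'moderate_positive': 293, 'none': 194,
 'moderate_negative': 9, 'strong_positive': 4}
...
chi-squared independence: stat=181.4, df=25, p=1.09e-25
permutation test (10,000 permutations): 11 of 36 cells associated at the 5% criterion

Fisher direction test on printed epithelial/fiber sets: p = 0.0003
```

The recovered global r of 0.543 is the planted 0.6 attenuated by count
noise; the chi-squared test rejects independence of the RNA and ATAC
cluster sets because the generator plants cluster co-membership; and the
Fisher p of 0.0003 reproduces the published association between
epithelial-identity genes (20 of 30 down-regulated, 2 up) and
fiber-identity genes (0 down, 5 up) after five days of vitreous exposure.
The other scripts in `examples/` each demonstrate one capability
(simulation, differential + clustering, annotation, TSS quintiles, motif
enrichment) in the same build–run–print style.

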