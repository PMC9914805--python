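"""TSS metaprofiles by expression quintile.

Genes are ranked by mean expression within each condition and split into
five equal bins (quintile 1 = highest).  Mean ATAC coverage in 10 bp bins
around the TSS (+/- 2 kb, strand-flipped so upstream is left) shows
accessibility tracking transcriptional output.
"""

from lenscape.differential import normalize, size_factors
from lenscape.integrate import tss_quintile_profiles
from lenscape.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_tss_coverage,
)

config = SimulationConfig(
    seed=1, n_genes=500, n_peaks=1500, chrom_sizes={"chr1": 8_000_000}
)
genes = simulate_annotation(config)
rna, atac, peaks, truth = simulate_counts(config, genes)
coverage, gene_ids = simulate_tss_coverage(config, genes, rna)
norm = normalize(rna, size_factors(rna))

profiles = tss_quintile_profiles(
    coverage, gene_ids, genes, norm, rna.sample_meta, atac.sample_meta
)

cond = "D5_DM"
mat = profiles[cond]
center = mat.shape[1] // 2
print(f"mean TSS-bin coverage by expression quintile ({cond}):")
for q in mat.index:
    print(f"  quintile {q} (1 = highest expression): {mat.loc[q].iloc[center]:.1f}")
print("\nhigher-expression quintiles carry proportionally stronger TSS "
      "accessibility signal, reproducing the expression-accessibility gradient.")
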