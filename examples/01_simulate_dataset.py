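"""Generate a synthetic explant-style dataset and write it to disk.

The generator emulates the six-condition lens explant design: a toy genome
annotation, RNA counts (3 replicates/condition), ATAC peak counts
(2 replicates/condition), one promoter peak per gene plus distal distractors,
and planted cluster/correlation/association structure with known ground truth.
"""

from pathlib import Path

from lenscape.io import write_gtf, write_peaks, write_tsv_matrix
from lenscape.simulate import SimulationConfig, simulate_annotation, simulate_counts

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(
    seed=1, n_genes=500, n_peaks=1500, chrom_sizes={"chr1": 8_000_000}
)
genes = simulate_annotation(config)
rna, atac, peaks, truth = simulate_counts(config, genes)

write_gtf(genes, out / "annotation.gtf")
write_peaks(peaks, out / "peaks.narrowPeak")
write_tsv_matrix(rna, out / "rna_counts.tsv")
write_tsv_matrix(atac, out / "atac_counts.tsv")
truth.rna_cluster.to_csv(out / "truth_rna_clusters.tsv", sep="\t")

n_signal = (truth.rna_cluster > 0).sum()
print(f"genes: {len(genes)} ({n_signal} with a planted condition archetype)")
print(f"RNA matrix: {rna.counts.shape[0]} genes x {rna.counts.shape[1]} samples")
print(f"ATAC matrix: {atac.counts.shape[0]} peaks x {atac.counts.shape[1]} samples")
print(f"planted expression<->promoter-accessibility correlation: "
      f"{config.rho_planted}")
print(f"files written under {out}/")
# Genes with cluster label 0 are null features (no condition effect): they
# anchor the size-factor normalization, exactly as non-differential genes do
# in real data.
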