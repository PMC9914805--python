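"""Synthetic data with planted structure emulating the explant study design.

The generator produces, deterministically under a fixed seed:

* a toy gene annotation (both strands, exon/intron/UTR structure, >= 6 kb
  inter-gene flanks),
* RNA and ATAC count matrices over the six-condition design (three RNA and
  two ATAC replicates per condition) with Gamma-Poisson (negative-binomial)
  noise around ``depth_factor * 2**latent`` means,
* one promoter peak per gene (anchor within 1 kb of the TSS) plus distal
  distractor peaks,
* planted expression archetypes: each gene (peak) belongs to one of k
  clusters whose mean log2 profile over conditions is a distinct archetype,
* a planted RNA-cluster x ATAC-cluster association: a gene's promoter-peak
  cluster is sampled conditionally on its RNA cluster with configurable odds,
* a planted per-gene correlation between expression and promoter
  accessibility, realized exactly at the latent level by a per-gene
  Gram-Schmidt construction (see docs/methods.md),
* TSS coverage profiles whose amplitude is monotone in expression, and
* peak sequences with motif instances planted at per-bin frequencies.

Ground truth (labels, assignments, latents) is returned alongside so every
downstream stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CONDITIONS, CountMatrix, GeneModel, PeakInterval, Pwm

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_archetypes",
    "simulate_annotation",
    "simulate_counts",
    "simulate_tss_coverage",
    "simulate_sequences",
]


def default_archetypes(k: int, scale: float = 2.0) -> np.ndarray:
    """k distinct, centered log2 condition profiles (k x 6).

    The base shapes loosely mimic the archetypes of the explant study
    (immediate-collection-high, vitreous-responsive, culture-time-responsive,
    ...); each row is mean-centered and multiplied by ``scale`` log2 units.
    """
    base = np.array(
        [
            #  IMD    D0  D1_CM D1_DM D5_CM D5_DM
            [1.0, -1.0, 0.0, 0.0, 0.5, 1.0],
            [0.0, 0.5, 0.0, 1.0, -1.0, 0.0],
            [1.0, 0.0, -0.5, -1.0, 0.0, -1.0],
            [-1.0, 0.0, 0.0, 1.0, 0.0, 1.0],
            [-1.0, 0.5, 0.5, 0.5, 0.5, 0.5],
            [1.0, 0.0, 1.0, -1.0, 1.0, -1.0],
        ]
    )
    if k > len(base):
        raise ValueError(f"at most {len(base)} default archetypes available")
    prof = base[:k]
    prof = prof - prof.mean(axis=1, keepdims=True)
    return prof * scale


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 2000
    n_peaks: int = 6000
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 20_000_000})
    rna_replicates: int = 3
    atac_replicates: int = 2
    n_rna_clusters: int = 6
    n_atac_clusters: int = 6
    archetype_scale: float = 2.0
    rna_archetypes: np.ndarray | None = None  # k x 6 log2 profiles
    atac_archetypes: np.ndarray | None = None
    dispersion: float = 0.05
    depth_factor_sd: float = 0.2  # lognormal sigma for library-size factors
    depth_factors: dict[str, float] | None = None
    association_odds: np.ndarray | None = None  # k_rna x k_atac; default: 5x at (6, 4)
    rho_planted: float | np.ndarray = 0.6
    #: fraction of features with no condition effect (flat profile, cluster
    #: label 0).  Keeping a majority of features null is what makes
    #: median-of-ratios size factors identifiable, as in real data where most
    #: genes are not differential.
    frac_null: float = 0.55
    rna_log2_mean: float = 7.0
    atac_log2_mean: float = 6.0
    baseline_sd: float = 0.5
    jitter_sd: float = 0.25
    min_flank: int = 6000
    gene_length_range: tuple[int, int] = (1500, 4000)
    max_exons: int = 4
    peak_width: int = 400
    coverage_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_peaks < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_rna_clusters < 1 or self.n_atac_clusters < 1:
            raise ValueError("cluster counts must be >= 1")
        rho = np.atleast_1d(np.asarray(self.rho_planted, dtype=float))
        if (np.abs(rho) > 1).any():
            raise ValueError("|rho_planted| must be <= 1")
        if self.rna_archetypes is None:
            self.rna_archetypes = default_archetypes(
                self.n_rna_clusters, self.archetype_scale
            )
        if self.atac_archetypes is None:
            self.atac_archetypes = default_archetypes(
                self.n_atac_clusters, self.archetype_scale
            )
        if self.association_odds is None:
            odds = np.ones((self.n_rna_clusters, self.n_atac_clusters))
            # emulate one strongly associated cluster pair (cf. the C6 x CD
            # association of the explant study)
            if self.n_rna_clusters >= 6 and self.n_atac_clusters >= 4:
                odds[5, 3] = 5.0
            self.association_odds = odds
        self.association_odds = np.asarray(self.association_odds, dtype=float)
        if (self.association_odds <= 0).any():
            raise ValueError("association odds must be positive")

    def rho_per_gene(self) -> np.ndarray:
        rho = np.asarray(self.rho_planted, dtype=float)
        if rho.ndim == 0:
            return np.full(self.n_genes, float(rho))
        if len(rho) != self.n_genes:
            raise ValueError("per-gene rho_planted must have length n_genes")
        return rho

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                v = v.tolist()
            data[k] = v
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted labels and assignments for recovery testing."""

    rna_cluster: pd.Series  # gene_id -> 0..k (0 = null feature, no effect)
    atac_cluster: pd.Series  # peak_id -> 0..k
    peak_gene: pd.Series  # peak_id -> intended gene_id (promoter peaks)
    rho: pd.Series  # gene_id -> planted correlation
    rna_latent: pd.DataFrame  # gene x condition log2 means
    atac_latent: pd.DataFrame  # peak x condition log2 means


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes with >= ``min_flank`` bp gaps on the toy genome."""
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes.items())
    n = config.n_genes
    if n == 0:
        return []
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    # distribute genes across chromosomes proportionally to length
    sizes = np.array([s for _, s in chroms], dtype=float)
    per_chrom = np.floor(sizes / sizes.sum() * n).astype(int)
    per_chrom[0] += n - per_chrom.sum()

    models: list[GeneModel] = []
    gi = 0
    for (chrom, size), n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        lens = lengths[gi: gi + n_c]
        need = int(lens.sum()) + (n_c + 1) * config.min_flank
        if need > size:
            raise ValueError(
                f"cannot place {n_c} genes on {chrom} ({size} bp): need {need} bp; "
                "use larger chromosomes or fewer genes"
            )
        slack = size - need
        # random partition of the slack over the n_c + 1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=n_c)) if slack > 0 else np.zeros(n_c, dtype=int)
        extra = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for j in range(n_c):
            pos += config.min_flank + int(extra[j])
            start1 = pos + 1  # 1-based
            end1 = pos + int(lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                _build_gene(f"g{gi + j:05d}", chrom, strand, start1, end1, rng, config)
            )
            pos = end1
        gi += n_c
    return models


def _build_gene(
    gene_id: str, chrom: str, strand: str, start1: int, end1: int,
    rng: np.random.Generator, config: SimulationConfig,
) -> GeneModel:
    """Split a span into alternating exon/intron chunks and carve UTRs."""
    length = end1 - start1 + 1
    max_ex = min(config.max_exons, max(1, length // 300))
    n_ex = int(rng.integers(1, max_ex + 1))
    n_chunks = 2 * n_ex - 1
    # chunk lengths: at least 100 bp each, remainder split randomly
    min_chunk = 100
    remainder = length - n_chunks * min_chunk
    w = rng.dirichlet(np.ones(n_chunks))
    chunk = (min_chunk + np.floor(w * remainder)).astype(int)
    chunk[-1] += length - chunk.sum()
    bounds = np.concatenate([[0], np.cumsum(chunk)])
    exons = []
    for j in range(n_ex):
        s = start1 + int(bounds[2 * j])
        e = start1 + int(bounds[2 * j + 1]) - 1
        exons.append((s, e))
    # UTRs sit at the transcript ends: 5' in the first exon (transcription
    # order), 3' in the last
    ordered = sorted(exons, reverse=strand == "-")
    f_s, f_e = ordered[0]
    l_s, l_e = ordered[-1]
    u5_len = min(150, (f_e - f_s + 1) // 3)
    u3_len = min(150, (l_e - l_s + 1) // 3)
    if strand == "+":
        utr5 = [(f_s, f_s + u5_len - 1)] if u5_len > 0 else []
        utr3 = [(l_e - u3_len + 1, l_e)] if u3_len > 0 else []
    else:
        utr5 = [(f_e - u5_len + 1, f_e)] if u5_len > 0 else []
        utr3 = [(l_s, l_s + u3_len - 1)] if u3_len > 0 else []
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tx_start=start1, tx_end=end1,
        exons=exons, utr5=utr5, utr3=utr3,
    )


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _sample_ids(modality: str, reps: int) -> tuple[list[str], pd.DataFrame]:
    ids, conds, r = [], [], []
    for cond in CONDITIONS:
        for rep in range(1, reps + 1):
            ids.append(f"{modality}_{cond}_{rep}")
            conds.append(cond)
            r.append(rep)
    meta = pd.DataFrame({"condition": conds, "replicate": r}, index=ids)
    return ids, meta


def _nb_counts(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson counts; at dispersion 0 the rounded means themselves."""
    if dispersion <= 0:
        return np.rint(means).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * means)
    return rng.poisson(lam).astype(np.int64)


def _orthonormal_residual(
    x_hat: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit vector in span-orthogonal-to-x_hat direction closest to y (centered)."""
    y0 = y - y.mean()
    resid = y0 - (y0 @ x_hat) * x_hat
    nrm = np.linalg.norm(resid)
    if nrm < 1e-9:
        z = rng.standard_normal(len(y))
        z -= z.mean()
        z -= (z @ x_hat) * x_hat
        nrm = np.linalg.norm(z)
        resid = z
    return resid / nrm


def simulate_counts(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[CountMatrix, CountMatrix, list[PeakInterval], GroundTruth]:
    """Generate RNA and ATAC count matrices, peaks, and the ground truth."""
    if config.n_peaks < config.n_genes:
        raise ValueError("n_peaks must be >= n_genes (one promoter peak per gene)")
    rng = np.random.default_rng(config.seed + 1)
    n_g = len(genes)
    gene_ids = [g.gene_id for g in genes]
    k_r, k_a = config.n_rna_clusters, config.n_atac_clusters
    n_cond = len(CONDITIONS)

    # --- cluster labels (0 = null feature, no condition effect) -----------
    null_gene = rng.random(n_g) < config.frac_null
    rna_lab = np.where(null_gene, 0, rng.integers(1, k_r + 1, size=n_g))
    marg = np.ones(k_a) / k_a
    atac_lab_prom = np.zeros(n_g, dtype=int)
    for i in range(n_g):
        if rna_lab[i] == 0:
            continue
        w = marg * config.association_odds[rna_lab[i] - 1]
        atac_lab_prom[i] = rng.choice(k_a, p=w / w.sum()) + 1

    n_distal = config.n_peaks - n_g
    null_distal = rng.random(n_distal) < config.frac_null
    atac_lab_distal = np.where(
        null_distal, 0, rng.integers(1, k_a + 1, size=n_distal)
    )

    # --- peaks ------------------------------------------------------------
    width = config.peak_width
    peaks: list[PeakInterval] = []
    for i, g in enumerate(genes):
        offset = int(rng.integers(-800, 801))  # anchor within 1 kb of the TSS
        anchor = g.tss0 + offset
        start = max(0, anchor - width // 2)
        peaks.append(
            PeakInterval(
                chrom=g.chrom, start=start, end=start + width,
                peak_id=f"prom_{g.gene_id}", summit_offset=anchor - start,
            )
        )
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss0)
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    chrom_names = list(config.chrom_sizes)
    for j in range(n_distal):
        for _ in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            anchor = int(rng.integers(width, config.chrom_sizes[chrom] - width))
            tss = tss_by_chrom.get(chrom)
            if tss is not None and len(tss):
                i = np.searchsorted(tss, anchor)
                near = min(
                    abs(anchor - tss[max(0, i - 1)]), abs(anchor - tss[min(len(tss) - 1, i)])
                )
                if near <= 3500:  # keep distractors out of promoter windows
                    continue
            break
        start = anchor - width // 2
        peaks.append(
            PeakInterval(
                chrom=chrom, start=start, end=start + width,
                peak_id=f"distal_{j:05d}", summit_offset=width // 2,
            )
        )
    peak_ids = [p.peak_id for p in peaks]

    # --- latent log2 condition profiles ------------------------------------
    rho = config.rho_per_gene()
    # archetype row 0 (null features) is flat
    arch_r = np.vstack([np.zeros(n_cond), config.rna_archetypes])
    arch_a = np.vstack([np.zeros(n_cond), config.atac_archetypes])
    b_rna = config.rna_log2_mean + config.baseline_sd * rng.standard_normal(n_g)
    jit_r = config.jitter_sd * rng.standard_normal((n_g, n_cond))
    rna_latent = b_rna[:, None] + arch_r[rna_lab] + jit_r

    # promoter-peak profiles: exact planted correlation with the gene profile
    b_std = (b_rna - b_rna.mean()) / (b_rna.std() or 1.0)
    atac_latent = np.empty((config.n_peaks, n_cond))
    jit_a = config.jitter_sd * rng.standard_normal((n_g, n_cond))
    u = rng.standard_normal(n_g)
    for i in range(n_g):
        x = rna_latent[i] - rna_latent[i].mean()
        nx = np.linalg.norm(x)
        y = arch_a[atac_lab_prom[i]] + jit_a[i]
        amp = np.linalg.norm(y - y.mean())
        r_i = rho[i] if nx > 0 else 0.0
        x_hat = x / nx if nx > 0 else np.zeros(n_cond)
        y_hat = _orthonormal_residual(x_hat, y, rng)
        within = amp * (r_i * x_hat + np.sqrt(max(0.0, 1 - r_i**2)) * y_hat)
        baseline = config.atac_log2_mean + config.baseline_sd * (
            r_i * b_std[i] + np.sqrt(max(0.0, 1 - r_i**2)) * u[i]
        )
        atac_latent[i] = baseline + within
    b_atac_d = config.atac_log2_mean + config.baseline_sd * rng.standard_normal(n_distal)
    jit_d = config.jitter_sd * rng.standard_normal((n_distal, n_cond))
    atac_latent[n_g:] = b_atac_d[:, None] + arch_a[atac_lab_distal] + jit_d

    # --- counts -----------------------------------------------------------
    rna_ids, rna_meta = _sample_ids("rna", config.rna_replicates)
    atac_ids, atac_meta = _sample_ids("atac", config.atac_replicates)
    if config.depth_factors is not None:
        depth_r = np.array([config.depth_factors[s] for s in rna_ids])
        depth_a = np.array([config.depth_factors[s] for s in atac_ids])
    else:
        depth_r = np.exp(config.depth_factor_sd * rng.standard_normal(len(rna_ids)))
        depth_a = np.exp(config.depth_factor_sd * rng.standard_normal(len(atac_ids)))

    cond_idx_r = np.array([CONDITIONS.index(c) for c in rna_meta["condition"]])
    cond_idx_a = np.array([CONDITIONS.index(c) for c in atac_meta["condition"]])
    mean_r = depth_r[None, :] * 2.0 ** rna_latent[:, cond_idx_r]
    mean_a = depth_a[None, :] * 2.0 ** atac_latent[:, cond_idx_a]
    counts_r = _nb_counts(mean_r, config.dispersion, rng)
    counts_a = _nb_counts(mean_a, config.dispersion, rng)

    rna = CountMatrix(pd.DataFrame(counts_r, index=gene_ids, columns=rna_ids), rna_meta)
    atac = CountMatrix(pd.DataFrame(counts_a, index=peak_ids, columns=atac_ids), atac_meta)

    truth = GroundTruth(
        rna_cluster=pd.Series(rna_lab, index=gene_ids, name="rna_cluster"),
        atac_cluster=pd.Series(
            np.concatenate([atac_lab_prom, atac_lab_distal]),
            index=peak_ids, name="atac_cluster",
        ),
        peak_gene=pd.Series(
            gene_ids, index=peak_ids[:n_g], name="gene_id"
        ),
        rho=pd.Series(rho, index=gene_ids, name="rho"),
        rna_latent=pd.DataFrame(rna_latent, index=gene_ids, columns=list(CONDITIONS)),
        atac_latent=pd.DataFrame(atac_latent, index=peak_ids, columns=list(CONDITIONS)),
    )
    return rna, atac, peaks, truth


# ---------------------------------------------------------------------------
# TSS coverage
# ---------------------------------------------------------------------------


def simulate_tss_coverage(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rna: CountMatrix,
    window: int = 2000,
    bin_size: int = 10,
    bump_sd_bins: float = 15.0,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Per-ATAC-sample binned coverage around each TSS (default +/- 2 kb, 10 bp).

    The profile is a Gaussian bump centered on the TSS bin whose amplitude is
    the gene's mean expression in the sample's condition (so amplitude is
    monotone in expression), times multiplicative noise of relative SD
    ``config.coverage_noise``.  Arrays are in genome orientation.
    Returns (sample_id -> genes x bins array, gene id order).
    """
    gene_ids = [g.gene_id for g in genes]
    missing = set(gene_ids) - set(rna.feature_ids)
    if missing:
        raise ValueError("annotation and RNA matrix must share gene ids")
    rng = np.random.default_rng(config.seed + 2)
    n_bins = 2 * window // bin_size
    centers = np.arange(n_bins) + 0.5
    tss_bin = n_bins // 2 + 0.5
    bump = np.exp(-0.5 * ((centers - tss_bin) / bump_sd_bins) ** 2)

    cond_mean = (
        rna.counts.loc[gene_ids]
        .T.groupby(rna.sample_meta["condition"].values)
        .mean()
        .T
    )
    out: dict[str, np.ndarray] = {}
    _, atac_meta = _sample_ids("atac", config.atac_replicates)
    for sample_id, row in atac_meta.iterrows():
        amp = cond_mean[row["condition"]].to_numpy()
        cov = amp[:, None] * bump[None, :]
        if config.coverage_noise > 0:
            cov = cov * (
                1.0 + config.coverage_noise * rng.standard_normal(cov.shape)
            ).clip(min=0.0)
        out[sample_id] = cov
    return out, gene_ids


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_REV = str.maketrans("ACGT", "TGCA")


def simulate_sequences(
    peaks: Sequence[PeakInterval],
    pwms: Sequence[Pwm],
    plant_freq: Mapping[str, Mapping[str, float]],
    region_bins: Mapping[str, str],
    seed: int = 0,
) -> dict[str, str]:
    """Random peak sequences with consensus motif instances planted per bin.

    ``plant_freq[motif_id][bin_id]`` is the probability that a region of that
    bin carries one exact consensus instance of the motif (on a uniformly
    chosen strand, at a uniform position).  The background is i.i.d. uniform
    A/C/G/T.  Peak widths must be >= the motif length.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.motif_id: p for p in pwms}
    for motif_id in plant_freq:
        if motif_id not in by_id:
            raise ValueError(f"unknown motif {motif_id!r}")
    seqs: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for p in peaks:
        width = p.end - p.start
        seq = list("".join(bases[rng.integers(0, 4, size=width)]))
        bin_id = region_bins.get(p.peak_id)
        for motif_id, freqs in plant_freq.items():
            f = freqs.get(bin_id, 0.0) if bin_id is not None else 0.0
            if f <= 0 or rng.random() >= f:
                continue
            cons = by_id[motif_id].consensus()
            if width < len(cons):
                raise ValueError(
                    f"peak {p.peak_id} narrower than motif {motif_id}"
                )
            if rng.random() < 0.5:
                cons = cons.translate(_REV)[::-1]
            pos = int(rng.integers(0, width - len(cons) + 1))
            seq[pos: pos + len(cons)] = list(cons)
        seqs[p.peak_id] = "".join(seq)
    return seqs
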