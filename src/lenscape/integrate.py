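"""Integration of chromatin accessibility with gene expression.

This module links the two assays: peaks are matched to genes by nearest
promoter, gene-level accessibility is the mean over a gene's peaks, and the
two modalities are compared by

* a global Pearson correlation over all (gene, condition) pairs,
* per-gene correlations binned into strength categories,
* a cluster cross-table (RNA archetype x ATAC archetype) with a chi-squared
  independence test and a fixed-margin permutation association test
  (a cell is "associated" when fewer than 5% of permuted counts reach the
  observed count),
* direction-concordance tables for the CM-vs-DM comparison at a given day,
* a two-sided Fisher exact test on direction 2x2 tables, and
* TSS metaprofiles averaged within expression quintiles.

The RNA assay has three replicates per condition and the ATAC assay two, so
samples are paired at the condition level using per-condition replicate means
(the only well-defined default for the unequal design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotationRecord
from .io import GeneModel

__all__ = [
    "PeakGeneMap",
    "AssociationResult",
    "match_peaks_to_genes",
    "gene_level_atac",
    "condition_means",
    "global_correlation",
    "per_gene_correlation_categories",
    "cross_table",
    "chi_squared_independence",
    "permutation_association",
    "direction_concordance",
    "fisher_direction_test",
    "tss_quintile_profiles",
]


@dataclass
class PeakGeneMap:
    """peak -> (gene, signed TSS distance) assignment plus the inverse map."""

    peak_to_gene: dict[str, tuple[str, int]]
    gene_to_peaks: dict[str, list[str]]
    n_unassigned: int = 0

    def gene_of(self, peak_id: str) -> str:
        return self.peak_to_gene[peak_id][0]

    def nearest_peak(self, gene_id: str) -> str:
        """The gene's peak with the smallest |TSS distance| (tie: peak_id)."""
        peaks = self.gene_to_peaks[gene_id]
        return min(peaks, key=lambda p: (abs(self.peak_to_gene[p][1]), p))


def match_peaks_to_genes(records: Sequence[AnnotationRecord]) -> PeakGeneMap:
    """Build the peak-to-gene map from annotation records (nearest promoter).

    Peaks with no nearest gene (chromosome absent from the annotation) are
    excluded and counted in ``n_unassigned``.
    """
    p2g: dict[str, tuple[str, int]] = {}
    g2p: dict[str, list[str]] = {}
    unassigned = 0
    for r in records:
        if r.nearest_gene is None:
            unassigned += 1
            continue
        p2g[r.peak_id] = (r.nearest_gene, r.tss_distance)
        g2p.setdefault(r.nearest_gene, []).append(r.peak_id)
    return PeakGeneMap(p2g, g2p, n_unassigned=unassigned)


def gene_level_atac(atac_norm: pd.DataFrame, pg_map: PeakGeneMap) -> pd.DataFrame:
    """Gene x sample accessibility: arithmetic mean of each gene's peaks.

    All mapped peaks must be present in the matrix; genes with zero mapped
    peaks are simply absent from the output.
    """
    missing = set(pg_map.peak_to_gene) - set(atac_norm.index)
    if missing:
        raise ValueError(f"{len(missing)} mapped peak(s) absent from the ATAC matrix")
    gene_of = pd.Series({p: g for p, (g, _) in pg_map.peak_to_gene.items()})
    sub = atac_norm.loc[gene_of.index]
    out = sub.groupby(gene_of.values).mean()
    out.index.name = "gene_id"
    return out


def condition_means(values: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate columns to per-condition means."""
    cond = sample_meta.loc[values.columns, "condition"]
    return values.T.groupby(cond.values).mean().T


def _paired_condition_matrices(
    rna_norm: pd.DataFrame,
    atac_gene: pd.DataFrame,
    rna_meta: pd.DataFrame,
    atac_meta: pd.DataFrame,
    log2: bool,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rna_c = condition_means(rna_norm, rna_meta)
    atac_c = condition_means(atac_gene, atac_meta)
    genes = rna_c.index.intersection(atac_c.index)
    conds = [c for c in rna_c.columns if c in set(atac_c.columns)]
    if len(genes) < 1 or not conds:
        raise ValueError("need >= 1 shared gene and >= 1 shared condition")
    r = rna_c.loc[genes, conds]
    a = atac_c.loc[genes, conds]
    if log2:
        r = np.log2(r + 1.0)
        a = np.log2(a + 1.0)
    return r, a


def global_correlation(
    rna_norm: pd.DataFrame,
    atac_gene: pd.DataFrame,
    rna_meta: pd.DataFrame,
    atac_meta: pd.DataFrame,
    log2: bool = True,
) -> float:
    """Pearson r over all flattened (gene, condition) pairs of both assays.

    Values are per-condition replicate means of normalized counts, on a
    log2(x+1) scale by default.
    """
    r, a = _paired_condition_matrices(rna_norm, atac_gene, rna_meta, atac_meta, log2)
    if len(r.index) < 2:
        raise ValueError("global correlation needs >= 2 shared genes")
    x = r.to_numpy().ravel()
    y = a.to_numpy().ravel()
    if x.size < 2:
        raise ValueError("fewer than 2 paired values")
    return float(stats.pearsonr(x, y).statistic)


CORRELATION_CATEGORIES = (
    "strong_positive",
    "moderate_positive",
    "none",
    "moderate_negative",
    "strong_negative",
)


def per_gene_correlation_categories(
    rna_norm: pd.DataFrame,
    atac_gene: pd.DataFrame,
    rna_meta: pd.DataFrame,
    atac_meta: pd.DataFrame,
    moderate: float = 0.5,
    strong: float = 0.9,
    log2: bool = True,
) -> pd.DataFrame:
    """Per-gene Pearson r across matched conditions with strength categories.

    Category thresholds are configurable: |r| >= ``strong`` is strong,
    ``moderate`` <= |r| < ``strong`` is moderate, |r| < ``moderate`` is none.
    Genes with a zero-variance vector in either assay get an undefined r (NaN)
    and category ``none``.
    """
    r, a = _paired_condition_matrices(rna_norm, atac_gene, rna_meta, atac_meta, log2)
    x = r.to_numpy()
    y = a.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = (xc * yc).sum(axis=1) / (sx * sy)
    rr = np.where((sx == 0) | (sy == 0), np.nan, rr)

    cats = np.full(len(rr), "none", dtype=object)
    valid = ~np.isnan(rr)
    mag = np.abs(rr)
    pos = rr >= 0
    cats[valid & (mag >= strong) & pos] = "strong_positive"
    cats[valid & (mag >= strong) & ~pos] = "strong_negative"
    cats[valid & (mag >= moderate) & (mag < strong) & pos] = "moderate_positive"
    cats[valid & (mag >= moderate) & (mag < strong) & ~pos] = "moderate_negative"
    return pd.DataFrame({"r": rr, "category": cats}, index=r.index)


def cross_table(
    rna_clusters: pd.Series,
    atac_clusters: pd.Series,
    pg_map: PeakGeneMap,
    multi_peak: str = "nearest",
) -> pd.DataFrame:
    """Genes counted per (RNA cluster, ATAC cluster) pair.

    A gene's ATAC cluster is that of its nearest peak (smallest |TSS
    distance|) by default, or the majority cluster of its peaks with
    ``multi_peak="majority"``.  Only genes present in both labelings are
    counted.
    """
    if multi_peak not in {"nearest", "majority"}:
        raise ValueError(f"unknown multi_peak rule {multi_peak!r}")
    gene_atac: dict[str, object] = {}
    for gene, peaks in pg_map.gene_to_peaks.items():
        labeled = [p for p in peaks if p in atac_clusters.index]
        if not labeled:
            continue
        if multi_peak == "nearest":
            p = min(labeled, key=lambda q: (abs(pg_map.peak_to_gene[q][1]), q))
            gene_atac[gene] = atac_clusters[p]
        else:
            vals = pd.Series([atac_clusters[p] for p in labeled])
            gene_atac[gene] = vals.mode().iloc[0]
    gene_atac = pd.Series(gene_atac)
    genes = rna_clusters.index.intersection(gene_atac.index)
    table = pd.crosstab(rna_clusters.loc[genes], gene_atac.loc[genes])
    table = table.reindex(
        index=sorted(rna_clusters.unique()), columns=sorted(atac_clusters.unique()),
        fill_value=0,
    )
    table.index.name = "rna_cluster"
    table.columns.name = "atac_cluster"
    return table


def chi_squared_independence(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a cross-table.

    Returns (statistic, df, p).  Requires all margins positive.
    """
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("cross-table has a zero margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class AssociationResult:
    """Per-cell permutation outcomes for a cluster cross-table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    empirical_p: pd.DataFrame
    associated: pd.DataFrame  # empirical_p < alpha
    n_perm: int
    alpha: float
    seed: int


def permutation_association(
    rna_labels: pd.Series | np.ndarray,
    atac_labels: pd.Series | np.ndarray,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    batch: int = 250,
) -> AssociationResult:
    """Fixed-margin permutation test of cluster co-membership, per cell.

    One label vector is uniformly permuted ``n_perm`` times (distributionally
    identical to permuting both, since only the relative alignment matters);
    for each permutation the cross-table is recomputed, and each cell's
    empirical p is the fraction of permutations whose count reaches the
    observed count.  A cell is associated when ``empirical_p < alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rna = pd.Series(np.asarray(rna_labels))
    atac = pd.Series(np.asarray(atac_labels))
    if len(rna) != len(atac):
        raise ValueError("label vectors must cover the same gene universe")
    r_levels = sorted(rna.unique())
    a_levels = sorted(atac.unique())
    r_codes = rna.map({v: i for i, v in enumerate(r_levels)}).to_numpy()
    a_codes = atac.map({v: i for i, v in enumerate(a_levels)}).to_numpy()
    R, A = len(r_levels), len(a_levels)
    n = len(r_codes)

    obs = np.bincount(r_codes * A + a_codes, minlength=R * A).reshape(R, A)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()

    rng = np.random.default_rng(seed)
    exceed = np.zeros((R, A), dtype=np.int64)
    done = 0
    base = np.tile(a_codes, (batch, 1))
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(base[:b], axis=1)
        codes = r_codes[None, :] * A + perm
        codes += (np.arange(b) * (R * A))[:, None]
        counts = np.bincount(codes.ravel(), minlength=b * R * A).reshape(b, R, A)
        exceed += (counts >= obs[None, :, :]).sum(axis=0)
        done += b

    emp_p = exceed / n_perm
    idx = pd.Index(r_levels, name="rna_cluster")
    cols = pd.Index(a_levels, name="atac_cluster")
    return AssociationResult(
        observed=pd.DataFrame(obs, index=idx, columns=cols),
        expected=pd.DataFrame(expected, index=idx, columns=cols),
        empirical_p=pd.DataFrame(emp_p, index=idx, columns=cols),
        associated=pd.DataFrame(emp_p < alpha, index=idx, columns=cols),
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )


DIRECTION_LEVELS = ("up_first", "no_difference", "up_second")


def direction_concordance(
    rna_up_first: set[str],
    rna_up_second: set[str],
    atac_up_first: set[str],
    atac_up_second: set[str],
    pg_map: PeakGeneMap,
) -> pd.DataFrame:
    """3x3 tally of accessibility direction vs expression direction.

    Every mapped peak is tallied by (its own differential-accessibility
    direction, the expression direction of its nearest gene) for one
    CM-vs-DM comparison; "first"/"second" refer to the two conditions of the
    comparison (e.g. up_first = up in CM, up_second = up in DM).  Peaks whose
    gene is absent from both expression direction sets count as
    ``no_difference`` for RNA; the table's grand total equals the number of
    mapped peaks.
    """
    table = pd.DataFrame(
        0,
        index=pd.Index(DIRECTION_LEVELS, name="rna"),
        columns=pd.Index(DIRECTION_LEVELS, name="atac"),
    )
    for peak, (gene, _) in pg_map.peak_to_gene.items():
        if peak in atac_up_first:
            a = "up_first"
        elif peak in atac_up_second:
            a = "up_second"
        else:
            a = "no_difference"
        if gene in rna_up_first:
            r = "up_first"
        elif gene in rna_up_second:
            r = "up_second"
        else:
            r = "no_difference"
        table.loc[r, a] += 1
    return table


def fisher_direction_test(
    set_a_down: int, set_a_up: int, set_b_down: int, set_b_up: int
) -> float:
    """Two-sided Fisher exact p for a 2x2 direction table.

    Rows are two gene sets (e.g. epithelial-identity vs fiber-identity
    genes), columns are regulation direction counts (down, up).
    """
    table = np.array([[set_a_down, set_a_up], [set_b_down, set_b_up]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def tss_quintile_profiles(
    coverage: Mapping[str, np.ndarray],
    coverage_gene_ids: Sequence[str],
    genes: Sequence[GeneModel],
    rna_norm: pd.DataFrame,
    rna_meta: pd.DataFrame,
    atac_meta: pd.DataFrame,
    n_quantiles: int = 5,
) -> dict[str, pd.DataFrame]:
    """Mean TSS coverage per expression quintile, per condition.

    ``coverage`` maps ATAC sample ids to (gene x position-bin) arrays in
    genome orientation.  Within each condition, genes are ranked by mean
    expression over RNA replicates (ties broken by a stable sort on gene id),
    split into ``n_quantiles`` equal-size bins with the remainder going to
    the lowest-expression bins, and each gene's coverage row (replicate mean,
    flipped for minus-strand genes so upstream is left) is averaged per bin.
    Quintile 1 is the highest-expression bin.
    """
    gene_ids = list(coverage_gene_ids)
    strand = {g.gene_id: g.strand for g in genes}
    missing = [g for g in gene_ids if g not in strand]
    if missing:
        raise ValueError(f"coverage gene ids absent from annotation: {missing[:3]}...")
    if len(gene_ids) < n_quantiles:
        raise ValueError(f"need >= {n_quantiles} genes")

    rna_c = condition_means(rna_norm.loc[gene_ids], rna_meta)
    flip = np.array([strand[g] == "-" for g in gene_ids])

    out: dict[str, pd.DataFrame] = {}
    for cond in rna_c.columns:
        atac_samples = list(atac_meta.index[atac_meta["condition"] == cond])
        atac_samples = [s for s in atac_samples if s in coverage]
        if not atac_samples:
            continue
        cov = np.mean([np.asarray(coverage[s], dtype=float) for s in atac_samples], axis=0)
        cov = cov.copy()
        cov[flip] = cov[flip, ::-1]

        expr = rna_c[cond]
        order = expr.iloc[np.argsort(expr.index.to_numpy(), kind="stable")]
        order = order.sort_values(ascending=False, kind="stable")
        row_of = {g: i for i, g in enumerate(gene_ids)}
        ranked = [row_of[g] for g in order.index]

        n = len(ranked)
        base, rem = divmod(n, n_quantiles)
        # remainder genes go to the lowest-expression (last) bins
        sizes = [base + (1 if q >= n_quantiles - rem else 0) for q in range(n_quantiles)]
        profiles = []
        pos = 0
        for size in sizes:
            rows = ranked[pos: pos + size]
            profiles.append(cov[rows].mean(axis=0))
            pos += size
        out[cond] = pd.DataFrame(
            np.vstack(profiles),
            index=pd.RangeIndex(1, n_quantiles + 1, name="quintile"),
        )
    return out
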