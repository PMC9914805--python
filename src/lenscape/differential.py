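"""Size-factor normalization, a stand-in differential test, and DEG/DAR calling.

Normalization follows the median-of-ratios definition: each sample's factor is
the median, over reference features (those with all-positive counts), of the
ratio of the sample's count to the feature's geometric mean across samples.

The differential test here is a deliberately simple stand-in: log2 fold change
from pseudo-counted group means of normalized counts, a Welch t-test on
log2(normalized + 1), and Benjamini-Hochberg adjustment within each pairwise
comparison.  Externally computed differential tables (e.g. negative-binomial
GLM results) can be supplied instead via :func:`read_diff_table`; everything
downstream consumes only the (feature, lfc, pvalue, padj) contract.

Differential features are called with inclusive thresholds |LFC| >= 1.5 and
adjusted p <= 0.05, and the non-redundant DEG/DAR set is the union over the
fifteen pairwise comparisons of the six-condition design.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

__all__ = [
    "FIFTEEN_COMPARISONS",
    "size_factors",
    "normalize",
    "differential_standin",
    "bh_adjust",
    "call_significant",
    "nonredundant_union",
    "run_all_comparisons",
    "read_diff_table",
]

#: The fifteen pairwise comparisons of the six-condition design, enumerated in
#: the order (baseline, treatment): all unordered pairs of
#: IMD, D0, D1_CM, D1_DM, D5_CM, D5_DM.
FIFTEEN_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("IMD", "D0"),
    ("IMD", "D1_CM"),
    ("IMD", "D5_CM"),
    ("IMD", "D1_DM"),
    ("IMD", "D5_DM"),
    ("D0", "D1_CM"),
    ("D0", "D5_CM"),
    ("D0", "D1_DM"),
    ("D0", "D5_DM"),
    ("D1_CM", "D5_CM"),
    ("D1_CM", "D1_DM"),
    ("D1_DM", "D5_DM"),
    ("D1_CM", "D5_DM"),
    ("D1_DM", "D5_CM"),
    ("D5_DM", "D5_CM"),
)

DIFF_COLUMNS = ["feature_id", "lfc", "pvalue", "padj", "comparison"]


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (one positive real per sample).

    Only features with all-positive counts serve as references.  Raises if no
    such feature exists.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference features (all-positive counts) for size factors")
    sub = counts[ref]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's column by its size factor (real-valued result)."""
    missing = set(matrix.sample_ids) - set(factors.index)
    if missing:
        raise ValueError(f"missing size factors for samples: {sorted(missing)}")
    if (factors.loc[matrix.sample_ids] <= 0).any():
        raise ValueError("size factors must be positive")
    return matrix.counts / factors.loc[matrix.sample_ids]


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_standin(
    matrix: CountMatrix,
    condition_a: str,
    condition_b: str,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    moderated: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Stand-in per-feature differential test between two conditions.

    Returns a DataFrame with columns ``feature_id, lfc, pvalue, padj,
    comparison`` where ``lfc = log2((mean_b + pc) / (mean_a + pc))`` on
    normalized counts and the p-value comes from a Welch t-test on
    log2(normalized + 1).  Requires >= 2 replicates per condition.

    With ``moderated=True`` the per-feature pooled variance is shrunk toward
    the median variance across features (``prior_df`` pseudo-observations)
    and the t statistic gains the prior degrees of freedom — the standard
    remedy when a design has very few replicates (e.g. two accessibility
    replicates per condition), where an unmoderated t has almost no power.
    """
    samples_a = matrix.samples_for(condition_a)
    samples_b = matrix.samples_for(condition_b)
    if not samples_a or not samples_b:
        missing = condition_a if not samples_a else condition_b
        raise ValueError(f"condition {missing!r} absent from sample metadata")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if factors is None:
        factors = size_factors(matrix)
    norm = normalize(matrix, factors)
    a = norm[samples_a].to_numpy()
    b = norm[samples_b].to_numpy()
    lfc = np.log2((b.mean(axis=1) + pseudocount) / (a.mean(axis=1) + pseudocount))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if moderated:
        pvals = _moderated_t(la, lb, prior_df)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # zero-variance ties
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "lfc": lfc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "comparison": f"{condition_a}_vs_{condition_b}",
        }
    )


def _moderated_t(la: np.ndarray, lb: np.ndarray, prior_df: float) -> np.ndarray:
    """Equal-variance t with the pooled variance shrunk toward its median."""
    na, nb = la.shape[1], lb.shape[1]
    df = na + nb - 2
    ss = la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    s2_prior = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1e-8
    s2_mod = (prior_df * s2_prior + df * s2) / (prior_df + df)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    t = (lb.mean(axis=1) - la.mean(axis=1)) / se
    return 2.0 * stats.t.sf(np.abs(t), df=prior_df + df)


def call_significant(
    results: pd.DataFrame, lfc_min: float = 1.5, padj_max: float = 0.05
) -> pd.DataFrame:
    """Filter one comparison's results to significant features with direction.

    A feature is kept iff |lfc| >= lfc_min AND padj <= padj_max (both
    thresholds inclusive).  Direction is ``up`` for positive lfc (higher in
    the second condition), ``down`` otherwise.
    """
    if results["comparison"].nunique() > 1:
        raise ValueError("call_significant expects results from one comparison")
    keep = (results["lfc"].abs() >= lfc_min) & (results["padj"] <= padj_max)
    out = results.loc[keep, ["feature_id", "lfc", "padj", "comparison"]].copy()
    out["direction"] = np.where(out["lfc"] >= 0, "up", "down")
    return out.reset_index(drop=True)


def nonredundant_union(all_comparisons: Mapping[str, pd.DataFrame]) -> list[str]:
    """Union of significant feature ids over comparisons, lexicographically sorted.

    ``all_comparisons`` maps a comparison label to the output of
    :func:`call_significant` for that comparison.  Duplicate labels cannot
    occur in a Mapping; passing a list of (label, frame) pairs with duplicated
    labels raises.
    """
    if not isinstance(all_comparisons, Mapping):
        labels = [lab for lab, _ in all_comparisons]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicated comparison label")
        all_comparisons = dict(all_comparisons)
    union: set[str] = set()
    for frame in all_comparisons.values():
        union.update(frame["feature_id"])
    return sorted(union)


def run_all_comparisons(
    matrix: CountMatrix,
    comparisons: Iterable[tuple[str, str]] = FIFTEEN_COMPARISONS,
    lfc_min: float = 1.5,
    padj_max: float = 0.05,
    moderated: bool = False,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Run the stand-in test for every comparison and return (per-comparison
    significant tables, non-redundant union of feature ids)."""
    factors = size_factors(matrix)
    sig: dict[str, pd.DataFrame] = {}
    for cond_a, cond_b in comparisons:
        res = differential_standin(
            matrix, cond_a, cond_b, factors=factors, moderated=moderated
        )
        sig[f"{cond_a}_vs_{cond_b}"] = call_significant(res, lfc_min, padj_max)
    return sig, nonredundant_union(sig)


def read_diff_table(path: str | Path) -> pd.DataFrame:
    """Read an externally computed differential table.

    Expects TSV columns ``feature_id, lfc, pvalue, padj, comparison`` (the
    export shape of standard differential pipelines).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(DIFF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[DIFF_COLUMNS].copy()
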