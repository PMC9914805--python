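"""K-means archetype clustering of differential feature sets.

Features (genes or peaks) are row z-scored (mean 0, SD 1 across samples)
before clustering so that cluster shapes are comparable across expression or
accessibility magnitudes, then partitioned with the Hartigan-Wong K-means
algorithm: after a Lloyd pass to near-convergence, points are reassigned one
at a time whenever moving a point from its cluster c to another cluster d
lowers the total within-cluster sum of squares, using the exact transfer
costs n_c/(n_c-1) * d(x, mu_c)^2 and n_d/(n_d+1) * d(x, mu_d)^2.  The best of
``n_start`` random initializations by inertia is kept, and the whole
procedure is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

__all__ = ["ClusterAssignment", "zscore_rows", "kmeans_features", "cluster_condition_profile"]


@dataclass
class ClusterAssignment:
    """Result of clustering: labels in 1..k, centroids, and total within-SS."""

    labels: pd.Series  # feature_id -> cluster label (1..k)
    k: int
    centroids: pd.DataFrame  # k x n_samples, index 1..k
    inertia: float
    algorithm: str = "hartigan-wong"

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row z-score; rows with zero variance are dropped with a warning."""
    arr = values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} constant feature row(s) before clustering")
    z = (arr[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=values.index[keep], columns=values.columns)


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int = 50):
    """Standard Lloyd iterations; returns (labels, centers) or None on empty cluster."""
    k = centers.shape[0]
    labels = np.zeros(len(x), dtype=int)
    for it in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if it > 0 and (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            mask = labels == c
            if not mask.any():
                return None
            centers[c] = x[mask].mean(axis=0)
    return labels, centers


def _hartigan_wong_sweeps(x: np.ndarray, labels: np.ndarray, centers: np.ndarray,
                          max_sweeps: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Sequential point-transfer sweeps; each accepted move strictly lowers SS."""
    k = centers.shape[0]
    counts = np.bincount(labels, minlength=k).astype(float)
    for _ in range(max_sweeps):
        moved = 0
        for i in range(len(x)):
            c = labels[i]
            if counts[c] <= 1:
                continue
            diff = centers - x[i]
            d2 = (diff * diff).sum(axis=1)
            remove_cost = counts[c] / (counts[c] - 1.0) * d2[c]
            gain = counts / (counts + 1.0) * d2
            gain[c] = np.inf
            d = int(gain.argmin())
            if gain[d] < remove_cost - 1e-12:
                # incremental centroid update
                centers[c] = (centers[c] * counts[c] - x[i]) / (counts[c] - 1.0)
                centers[d] = (centers[d] * counts[d] + x[i]) / (counts[d] + 1.0)
                counts[c] -= 1.0
                counts[d] += 1.0
                labels[i] = d
                moved += 1
        if moved == 0:
            break
    return labels, centers


def _inertia(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((x - centers[labels]) ** 2).sum())


def kmeans_features(
    values: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    n_start: int = 25,
    zscore: bool = True,
    algorithm: str = "hartigan-wong",
) -> ClusterAssignment:
    """Cluster feature rows into k archetypes.

    Parameters
    ----------
    values
        Normalized counts restricted to the selected (differential) features,
        features x samples.
    k
        Number of clusters (six archetypes by default, matching the explant
        study design).
    n_start
        Number of random initializations; the run with the lowest inertia
        wins.
    algorithm
        ``"hartigan-wong"`` (default) or ``"lloyd"``; the choice is recorded
        in the result metadata.
    """
    if algorithm not in {"hartigan-wong", "lloyd"}:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    data = zscore_rows(values) if zscore else values.copy()
    x = np.ascontiguousarray(data.to_numpy(dtype=float))
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of usable features ({n})")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_start):
        for _attempt in range(10):  # re-initialize on empty clusters
            idx = rng.choice(n, size=k, replace=False)
            centers = x[idx].copy()
            res = _lloyd(x, centers)
            if res is not None:
                break
        else:
            raise RuntimeError("could not initialize k-means without empty clusters")
        labels, centers = res
        if algorithm == "hartigan-wong":
            labels, centers = _hartigan_wong_sweeps(x, labels, centers)
        inertia = _inertia(x, labels, centers)
        if best is None or inertia < best[0]:
            best = (inertia, labels.copy(), centers.copy())

    inertia, labels, centers = best
    # relabel clusters deterministically (by first occurrence) into 1..k
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    # clusters never empty here, so all k labels appear
    relabeled = np.array([order[lab] for lab in labels])
    centroid_rows = np.empty_like(centers)
    for old, new in order.items():
        centroid_rows[new - 1] = centers[old]
    return ClusterAssignment(
        labels=pd.Series(relabeled, index=data.index, name="cluster"),
        k=k,
        centroids=pd.DataFrame(
            centroid_rows, index=pd.RangeIndex(1, k + 1, name="cluster"),
            columns=data.columns,
        ),
        inertia=inertia,
        algorithm=algorithm,
    )


def cluster_condition_profile(
    assignment: ClusterAssignment,
    values: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cluster mean z-score per condition (cluster x condition).

    ``values`` are normalized counts for the clustered features; rows are
    z-scored, then averaged over the features of each cluster and the
    replicate samples of each condition.
    """
    z = zscore_rows(values.loc[assignment.labels.index])
    cond = sample_meta.loc[z.columns, "condition"]
    by_cond = z.T.groupby(cond.values).mean().T  # features x conditions
    prof = by_cond.groupby(assignment.labels).mean()
    prof.index.name = "cluster"
    return prof
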