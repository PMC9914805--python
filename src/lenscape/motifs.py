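"""Binned motif over-representation in differentially accessible regions.

Region sequences are scanned with position weight matrices by log2-odds
scoring against the motif background; a window is a hit when its score
reaches ``score_fraction`` (default 0.8) of the maximum attainable score,
and both strands are scanned.  Regions are stratified by differential
accessibility: a center bin holds the non-differential zone (|LFC| below the
significance threshold) and the remaining regions are split into equal-count
bins per side by LFC rank.  Each (motif, bin) pair is then tested for hit
over-representation against all other bins with a one-sided (upper tail)
hypergeometric test; significance uses the stringent cutoff p < 5e-5.

GC content per bin is reported alongside, but no GC correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BASES, Pwm

__all__ = [
    "MotifHits",
    "LfcBin",
    "scan_pwm",
    "bin_regions_by_lfc",
    "bin_enrichment",
    "filter_regions_by_category",
    "gc_content",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(BASES + "N")}


@dataclass
class MotifHits:
    """Scan result for one motif over a set of regions."""

    motif_id: str
    hit: dict[str, bool]  # region -> any hit
    positions: dict[str, list[tuple[int, str, float]]]  # region -> (start, strand, score)
    threshold: float
    max_score: float

    @property
    def hit_regions(self) -> set[str]:
        return {r for r, h in self.hit.items() if h}


def _logodds_matrix(pwm: Pwm) -> np.ndarray:
    """5 x L log2-odds matrix; the extra N row scores 0 (background)."""
    lo = np.log2(pwm.matrix / pwm.background[:, None])
    return np.vstack([lo, np.zeros((1, pwm.length))])


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int64, count=len(seq)
    )


def _window_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window of an encoded sequence against a 5 x L matrix."""
    L = lo.shape[1]
    n = len(idx) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: Pwm,
    score_fraction: float = 0.8,
) -> MotifHits:
    """Scan each region sequence on both strands for motif hits.

    The hit threshold is ``score_fraction`` times the maximum attainable
    log2-odds score.  N bases contribute zero log-odds.  Sequences shorter
    than the motif simply have no hits.  Minus-strand hit positions refer to
    the window start on the forward sequence.
    """
    lo = _logodds_matrix(pwm)
    max_score = float(lo[:4].max(axis=0).sum())
    threshold = score_fraction * max_score
    hit: dict[str, bool] = {}
    positions: dict[str, list[tuple[int, str, float]]] = {}
    L = pwm.length
    for rid, seq in sequences.items():
        seq = seq.upper()
        found: list[tuple[int, str, float]] = []
        fwd = _window_scores(_encode(seq), lo)
        for i in np.nonzero(fwd >= threshold)[0]:
            found.append((int(i), "+", float(fwd[i])))
        rev = _window_scores(_encode(reverse_complement(seq)), lo)
        for i in np.nonzero(rev >= threshold)[0]:
            found.append((len(seq) - L - int(i), "-", float(rev[i])))
        positions[rid] = sorted(found)
        hit[rid] = bool(found)
    return MotifHits(
        motif_id=pwm.motif_id, hit=hit, positions=positions,
        threshold=threshold, max_score=max_score,
    )


@dataclass
class LfcBin:
    """A stratum of regions on the LFC axis."""

    bin_id: str
    lfc_range: tuple[float, float]  # half-open [lo, hi)
    region_ids: list[str]


def bin_regions_by_lfc(
    dar_results: pd.DataFrame,
    n_bins: int = 5,
    center_halfwidth: float = 1.5,
) -> list[LfcBin]:
    """Partition one comparison's regions into LFC bins around a center bin.

    The center bin holds |LFC| < ``center_halfwidth`` (the non-differential
    zone); each side's remaining regions are split into
    ``(n_bins - 1) / 2`` equal-count bins by LFC rank (sizes differing by at
    most 1), ordered most-negative first.  An empty side simply yields empty
    bins.  ``n_bins`` must be odd and >= 3.
    """
    if n_bins < 3 or n_bins % 2 == 0:
        raise ValueError("n_bins must be odd and >= 3")
    df = dar_results.sort_values(["lfc", "feature_id"], kind="stable")
    lfc = df["lfc"].to_numpy()
    ids = df["feature_id"].to_numpy()
    per_side = (n_bins - 1) // 2

    neg = ids[lfc <= -center_halfwidth]
    neg_lfc = lfc[lfc <= -center_halfwidth]
    pos = ids[lfc >= center_halfwidth]
    pos_lfc = lfc[lfc >= center_halfwidth]
    center = ids[np.abs(lfc) < center_halfwidth]

    def split(side_ids, side_lfc, k):
        # equal-count chunks in rank order; sizes differ by at most 1
        chunks_i = np.array_split(side_ids, k)
        chunks_l = np.array_split(side_lfc, k)
        return list(zip(chunks_i, chunks_l))

    bins: list[LfcBin] = []
    for j, (cid, clfc) in enumerate(split(neg, neg_lfc, per_side)):
        lo = float(clfc.min()) if len(clfc) else -np.inf
        hi = float(clfc.max()) if len(clfc) else -center_halfwidth
        bins.append(LfcBin(f"neg{per_side - j}", (lo, hi), list(cid)))
    bins.append(
        LfcBin("center", (-center_halfwidth, center_halfwidth), list(center))
    )
    for j, (cid, clfc) in enumerate(split(pos, pos_lfc, per_side)):
        lo = float(clfc.min()) if len(clfc) else center_halfwidth
        hi = float(clfc.max()) if len(clfc) else np.inf
        bins.append(LfcBin(f"pos{j + 1}", (lo, hi), list(cid)))
    return bins


def bin_enrichment(
    hits: Mapping[str, set[str]] | Sequence[MotifHits],
    bins: Sequence[LfcBin],
    p_cutoff: float = 5e-5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per (motif, bin).

    For each motif and bin: given ``total`` regions of which ``K`` carry the
    motif, the upper-tail probability that a bin of its size contains at
    least the observed number of motif regions.  ``log2_enrichment`` compares
    the bin's hit fraction to the rest with a pseudo-frequency of
    1/total.  Raises with a single bin (no background to compare against).
    """
    if len(bins) < 2:
        raise ValueError("need >= 2 bins (single bin has no background)")
    if isinstance(hits, Mapping):
        hit_sets = dict(hits)
    else:
        hit_sets = {h.motif_id: h.hit_regions for h in hits}
    region_bin: dict[str, str] = {}
    for b in bins:
        for rid in b.region_ids:
            if rid in region_bin:
                raise ValueError(f"region {rid} appears in more than one bin")
            region_bin[rid] = b.bin_id
    total = len(region_bin)
    if total == 0:
        raise ValueError("no regions in bins")
    eps = 1.0 / total

    rows = []
    for motif_id, hit_regions in sorted(hit_sets.items()):
        hit_in_universe = {r for r in hit_regions if r in region_bin}
        K = len(hit_in_universe)
        for b in bins:
            n_bin = len(b.region_ids)
            k = sum(r in hit_in_universe for r in b.region_ids)
            if n_bin == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k - 1, total, K, n_bin))
            frac_bin = k / n_bin if n_bin else 0.0
            rest_n = total - n_bin
            frac_rest = (K - k) / rest_n if rest_n else 0.0
            log2_enr = float(np.log2((frac_bin + eps) / (frac_rest + eps)))
            rows.append(
                {
                    "motif_id": motif_id,
                    "bin_id": b.bin_id,
                    "bin_size": n_bin,
                    "hit_regions": k,
                    "log2_enrichment": log2_enr,
                    "p": p,
                    "significant": p < p_cutoff,
                }
            )
    return pd.DataFrame(rows)


def filter_regions_by_category(
    dar_results: pd.DataFrame,
    records,
    categories,
) -> pd.DataFrame:
    """Restrict a DAR table to regions whose annotation category is listed.

    Used to run the motif analysis separately on promoter vs remaining
    accessible regions: pass the three promoter bins (or their complement)
    as ``categories`` together with the peak annotation records.
    """
    allowed = {r.peak_id for r in records if r.category in set(categories)}
    return dar_results[dar_results["feature_id"].isin(allowed)].copy()


def gc_content(sequences: Mapping[str, str], bins: Sequence[LfcBin]) -> pd.Series:
    """Mean GC fraction of the regions in each bin (reported, not corrected for)."""
    out = {}
    for b in bins:
        fracs = []
        for rid in b.region_ids:
            s = sequences[rid].upper()
            if s:
                fracs.append((s.count("G") + s.count("C")) / len(s))
        out[b.bin_id] = float(np.mean(fracs)) if fracs else np.nan
    return pd.Series(out, name="gc")
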