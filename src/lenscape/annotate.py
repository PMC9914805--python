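"""Genomic feature annotation of peaks: the eleven-category scheme.

Each peak is reduced to a single anchor point (the summit when available,
else the interval midpoint) and assigned exactly one category:

    Promoter<=1kb, Promoter1-2kb, Promoter2-3kb, FirstExon, OtherExon,
    FirstIntron, OtherIntron, UTR5, UTR3, Downstream<=300kb, DistalIntergenic

The TSS distance is signed in gene orientation: negative means upstream of
the TSS.  When the anchor satisfies several definitions, the precedence
ladder is

    promoter bins (by |distance| to the nearest TSS) > UTR5 > UTR3 >
    FirstExon > OtherExon > FirstIntron > OtherIntron > Downstream >
    DistalIntergenic

mirroring the default priority of the common nearest-TSS annotators.  The
downstream window (distance past a gene's 3' end, in gene orientation) is a
parameter; it defaults to 300 kb — the downstream-intergenic definition this
category scheme uses — even though many annotation tools default to 300 bp
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, PeakInterval

__all__ = [
    "CATEGORIES",
    "PROMOTER_CATEGORIES",
    "AnnotationRecord",
    "annotate_peaks",
    "feature_distribution",
    "promoter_split_summary",
    "fold_change",
]

CATEGORIES = (
    "Promoter<=1kb",
    "Promoter1-2kb",
    "Promoter2-3kb",
    "FirstExon",
    "OtherExon",
    "FirstIntron",
    "OtherIntron",
    "UTR5",
    "UTR3",
    "Downstream<=300kb",
    "DistalIntergenic",
)

PROMOTER_CATEGORIES = frozenset(
    {"Promoter<=1kb", "Promoter1-2kb", "Promoter2-3kb"}
)

#: precedence of genic sub-features once the promoter window is excluded
_GENIC_PRECEDENCE = ("UTR5", "UTR3", "FirstExon", "OtherExon", "FirstIntron", "OtherIntron")


@dataclass
class AnnotationRecord:
    peak_id: str
    category: str
    nearest_gene: str | None
    tss_distance: int | None


def _signed_distance(anchor0: int, gene: GeneModel) -> int:
    """Signed anchor->TSS distance in gene orientation (negative = upstream)."""
    if gene.strand == "+":
        return anchor0 - gene.tss0
    return gene.tss0 - anchor0


def _genic_category(anchor1: int, gene: GeneModel) -> str | None:
    """Sub-feature category of a 1-based position inside a gene body, or None."""
    if not (gene.tx_start <= anchor1 <= gene.tx_end):
        return None
    for s, e in gene.utr5:
        if s <= anchor1 <= e:
            return "UTR5"
    for s, e in gene.utr3:
        if s <= anchor1 <= e:
            return "UTR3"
    for j, (s, e) in enumerate(gene.exons):
        lo, hi = min(s, e), max(s, e)
        if lo <= anchor1 <= hi:
            return "FirstExon" if j == 0 else "OtherExon"
    for j, (s, e) in enumerate(gene.introns()):
        lo, hi = min(s, e), max(s, e)
        if lo <= anchor1 <= hi:
            return "FirstIntron" if j == 0 else "OtherIntron"
    return None


def annotate_peaks(
    peaks: Sequence[PeakInterval],
    genes: Sequence[GeneModel],
    promoter_bins: tuple[int, int, int] = (1000, 2000, 3000),
    downstream_window: int = 300_000,
) -> list[AnnotationRecord]:
    """Assign each peak one category, its nearest gene, and a signed TSS distance.

    Peaks on a chromosome absent from the annotation become DistalIntergenic
    with no nearest gene.  Nearest-gene ties (equal |distance|) break to the
    lexicographically smaller gene_id.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    # per-chromosome arrays for vectorized nearest-TSS search
    chrom_arrays: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gl in by_chrom.items():
        gl = sorted(gl, key=lambda g: g.gene_id)
        chrom_arrays[chrom] = (np.array([g.tss0 for g in gl]), gl)

    b1, b2, b3 = promoter_bins
    records: list[AnnotationRecord] = []
    for p in peaks:
        if p.chrom not in chrom_arrays:
            records.append(AnnotationRecord(p.peak_id, "DistalIntergenic", None, None))
            continue
        tss0, gl = chrom_arrays[p.chrom]
        anchor0 = p.anchor
        anchor1 = anchor0 + 1
        absd = np.abs(anchor0 - tss0)
        # genes sorted by gene_id, so argmin already breaks ties lexicographically
        gi = int(absd.argmin())
        gene = gl[gi]
        dist = _signed_distance(anchor0, gene)

        if abs(dist) <= b1:
            cat = "Promoter<=1kb"
        elif abs(dist) <= b2:
            cat = "Promoter1-2kb"
        elif abs(dist) <= b3:
            cat = "Promoter2-3kb"
        else:
            found = [c for g in gl if (c := _genic_category(anchor1, g)) is not None]
            if found:
                cat = min(found, key=_GENIC_PRECEDENCE.index)
            elif _is_downstream(anchor1, gl, downstream_window):
                cat = "Downstream<=300kb"
            else:
                cat = "DistalIntergenic"
        records.append(AnnotationRecord(p.peak_id, cat, gene.gene_id, int(dist)))
    return records


def _is_downstream(anchor1: int, genes: Iterable[GeneModel], window: int) -> bool:
    """True if the position lies within ``window`` bp past some gene's 3' end."""
    for g in genes:
        if g.strand == "+":
            if g.tx_end < anchor1 <= g.tx_end + window:
                return True
        else:
            if g.tx_start - window <= anchor1 < g.tx_start:
                return True
    return False


def feature_distribution(records: Sequence[AnnotationRecord]) -> pd.Series:
    """Percentage of peaks per category (all eleven categories, summing to 100)."""
    if not records:
        raise ValueError("no annotation records")
    counts = pd.Series(0, index=list(CATEGORIES), dtype=float)
    for r in records:
        counts[r.category] += 1
    return counts / counts.sum() * 100.0


def fold_change(earlier: int, later: int) -> float | None:
    """later/earlier rounded to one decimal; undefined (None) when earlier is 0."""
    if earlier == 0:
        return None
    return round(later / earlier, 1)


def promoter_split_summary(
    dars_by_comparison: Mapping[str, Iterable[str]],
    fold_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter vs non-promoter DAR counts per comparison, plus fold ratios.

    Parameters
    ----------
    dars_by_comparison
        Maps a comparison label (e.g. ``"D1_CM_up"``) to the annotation
        categories of its DARs.  "Promoter" means any of the three promoter
        distance bins.
    fold_pairs
        (earlier, later) label pairs for which promoter and non-promoter fold
        changes (later/earlier, 1-decimal) are reported; a zero earlier count
        yields an undefined (NaN) fold rather than infinity.

    Returns
    -------
    (counts, folds)
        ``counts`` has one row per comparison with ``n_promoter`` and
        ``n_nonpromoter``; ``folds`` has one row per pair with
        ``promoter_fold`` and ``nonpromoter_fold``.
    """
    rows = {}
    for label, cats in dars_by_comparison.items():
        cats = list(cats)
        n_prom = sum(c in PROMOTER_CATEGORIES for c in cats)
        rows[label] = {"n_promoter": n_prom, "n_nonpromoter": len(cats) - n_prom}
    counts = pd.DataFrame.from_dict(rows, orient="index")

    fold_rows = {}
    for earlier, later in fold_pairs:
        pf = fold_change(counts.loc[earlier, "n_promoter"], counts.loc[later, "n_promoter"])
        nf = fold_change(
            counts.loc[earlier, "n_nonpromoter"], counts.loc[later, "n_nonpromoter"]
        )
        fold_rows[f"{earlier}->{later}"] = {
            "promoter_fold": np.nan if pf is None else pf,
            "nonpromoter_fold": np.nan if nf is None else nf,
        }
    folds = pd.DataFrame.from_dict(fold_rows, orient="index")
    return counts, folds
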