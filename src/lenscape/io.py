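"""Readers and writers for the genomic and tabular formats used throughout.

Coordinate conventions
----------------------
GTF is 1-based inclusive; BED/narrowPeak is 0-based half-open.  All internal
interval arithmetic is done in 0-based half-open coordinates: peaks are stored
as parsed, and gene models keep their 1-based GTF coordinates but expose
``tss0`` (a 0-based TSS position) for distance math.  Conversion happens once,
at the parse boundary.

The six experimental conditions of the explant design (immediate collection,
24 h baseline, and day-1/day-5 culture medium or differentiation medium) form
a closed vocabulary; sample metadata naming any other condition is rejected
early.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CONDITIONS",
    "GeneModel",
    "PeakInterval",
    "CountMatrix",
    "Pwm",
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_peaks",
    "write_peaks",
    "read_jaspar",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_fasta",
    "write_fasta",
]

#: Closed vocabulary of experimental conditions: immediate collection (IMD),
#: 24 h in culture medium (D0), then one or five further days in culture
#: medium (CM) or vitreous-supplemented differentiation medium (DM).
CONDITIONS = ("IMD", "D0", "D1_CM", "D1_DM", "D5_CM", "D5_DM")

BASES = "ACGT"


class ParseError(ValueError):
    """A file violated the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One gene's coordinates on the genome, 1-based inclusive.

    ``exons`` are ordered 5'->3' in transcription order (descending start for
    minus-strand genes), non-overlapping, and nested within
    ``[tx_start, tx_end]``.  The TSS is the gene-level transcription start:
    ``tx_start`` on the plus strand, ``tx_end`` on the minus strand, using the
    union transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]
        for s, e in self.exons:
            if not (self.tx_start <= s <= e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
        # enforce 5'->3' transcription order
        self.exons = sorted(self.exons, reverse=self.strand == "-")
        for (_, e1), (s2, _) in zip(sorted(self.exons), sorted(self.exons)[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        """1-based TSS position (tx_start on +, tx_end on -)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tss0(self) -> int:
        """0-based TSS position."""
        return self.tss - 1

    @property
    def three_prime_end(self) -> int:
        """1-based position of the transcription end (3' terminus)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive), in transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


@dataclass
class PeakInterval:
    """An accessible-chromatin peak, 0-based half-open."""

    chrom: str
    start: int
    end: int
    peak_id: str = ""
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"peak {self.peak_id or '?'} ({self.chrom}:{self.start}-{self.end}): "
                "requires 0 <= start < end"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(f"peak {self.peak_id}: summit_offset out of range")

    @property
    def anchor(self) -> int:
        """0-based anchor point: the summit when present, else the midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


class CountMatrix:
    """Nonnegative integer counts, features x samples, plus sample metadata.

    ``sample_meta`` is indexed by sample_id with columns ``condition`` (drawn
    from :data:`CONDITIONS`) and ``replicate`` (positive integer).
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        sample_meta = sample_meta.copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate feature_ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample_ids")
        vals = counts.to_numpy()
        if vals.size and (
            not np.isfinite(vals).all() or (vals < 0).any() or (vals % 1 != 0).any()
        ):
            raise ValueError("counts must be finite nonnegative integers")
        if list(sample_meta.index) != list(counts.columns):
            sample_meta = sample_meta.loc[counts.columns]
        bad = set(sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")
        if (sample_meta["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive")
        self.counts = counts.astype(np.int64)
        self.sample_meta = sample_meta

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_of(self, sample_id: str) -> str:
        return self.sample_meta.loc[sample_id, "condition"]

    def samples_for(self, condition: str) -> list[str]:
        m = self.sample_meta["condition"] == condition
        return list(self.sample_meta.index[m])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples)"
        )


@dataclass
class Pwm:
    """A position probability matrix (rows A,C,G,T) with a background."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_utr", "5utr", "five_prime_UTR"}
_UTR3_TYPES = {"three_prime_utr", "3utr", "three_prime_UTR"}


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF2.2 file into gene-level models.

    Gene/transcript/exon/UTR feature lines are assembled per ``gene_id``.
    Exons from multiple transcripts are union-merged; the transcript span is
    the union span and the TSS is taken at gene level.  A gene with zero exon
    lines gets its transcript span as a single exon, with a warning.
    """
    import gffutils

    path = Path(path)
    text_lines = path.read_text().splitlines()
    for i, line in enumerate(text_lines, start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) < 9:
            raise ParseError(f"{path}: malformed GTF line {i}: fewer than 9 fields")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    genes: dict[str, dict] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(f"{path}: feature without gene_id at {feat.seqid}:{feat.start}")
        rec = genes.setdefault(
            gid,
            {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "start": feat.start,
                "end": feat.end,
                "exons": [],
                "utr5": [],
                "utr3": [],
            },
        )
        rec["start"] = min(rec["start"], feat.start)
        rec["end"] = max(rec["end"], feat.end)
        ftype = feat.featuretype.lower()
        if ftype == "exon":
            rec["exons"].append((feat.start, feat.end))
        elif ftype in {t.lower() for t in _UTR5_TYPES}:
            rec["utr5"].append((feat.start, feat.end))
        elif ftype in {t.lower() for t in _UTR3_TYPES}:
            rec["utr3"].append((feat.start, feat.end))

    models = []
    for gid, rec in genes.items():
        exons = _merge_intervals(rec["exons"])
        if not exons:
            warnings.warn(
                f"gene {gid} has no exon lines; using transcript span as one exon"
            )
            exons = [(rec["start"], rec["end"])]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tx_start=rec["start"],
                tx_end=rec["end"],
                exons=exons,
                utr5=_merge_intervals(rec["utr5"]),
                utr3=_merge_intervals(rec["utr3"]),
            )
        )
    models.sort(key=lambda g: (g.chrom, g.tx_start, g.gene_id))
    return models


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge 1-based inclusive intervals."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def write_gtf(models: Sequence[GeneModel], path: str | Path, source: str = "lenscape") -> None:
    """Write gene models as GTF2.2 (gene/transcript/exon/UTR lines)."""
    with open(path, "w") as fh:
        for g in sorted(models, key=lambda m: (m.chrom, m.tx_start, m.gene_id)):
            attrs_g = f'gene_id "{g.gene_id}";'
            attrs_t = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'

            def line(ftype: str, s: int, e: int, attrs: str) -> str:
                return (
                    f"{g.chrom}\t{source}\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            fh.write(line("gene", g.tx_start, g.tx_end, attrs_g))
            fh.write(line("transcript", g.tx_start, g.tx_end, attrs_t))
            for s, e in sorted(g.exons):
                fh.write(line("exon", s, e, attrs_t))
            for s, e in sorted(g.utr5):
                fh.write(line("five_prime_utr", s, e, attrs_t))
            for s, e in sorted(g.utr3):
                fh.write(line("three_prime_utr", s, e, attrs_t))


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[PeakInterval]:
    """Read peaks from BED3+ or ENCODE narrowPeak (10-column) files.

    narrowPeak column 10 (0-based summit offset from start) is stored as
    ``summit_offset``; a value of -1 means "no summit" and is stored as None.
    """
    if dialect not in {"BED", "narrowPeak"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[PeakInterval] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            min_cols = 10 if dialect == "narrowPeak" else 3
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}: line {i}: expected >= {min_cols} columns for {dialect}"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(
                    f"{path}: line {i}: start >= end in record {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"peak_{i}"
            summit = None
            if dialect == "narrowPeak":
                s = int(fields[9])
                summit = None if s == -1 else s
            peaks.append(
                PeakInterval(chrom=chrom, start=start, end=end, peak_id=name,
                             summit_offset=summit)
            )
    return peaks


def write_peaks(peaks: Sequence[PeakInterval], path: str | Path,
                dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "BED":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t0\t-1\t-1\t{summit}\n"
                )


# ---------------------------------------------------------------------------
# JASPAR
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path, pseudocount: float = 0.5) -> list[Pwm]:
    """Read JASPAR-format PFMs and convert counts to probabilities.

    A pseudocount (default 0.5 per cell) is added before column normalization
    so that log-odds scores stay finite.
    """
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            records = list(records)
        except Exception as exc:  # biopython raises bare Exceptions on bad input
            raise ParseError(f"{path}: {exc}") from exc
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        if counts.ndim != 2:
            raise ParseError(f"{path}: motif {m.matrix_id}: ragged count rows")
        counts = counts + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        out.append(Pwm(motif_id=m.matrix_id or m.name, matrix=probs, name=m.name or ""))
    return out


def write_jaspar(pwms_counts: dict[str, np.ndarray], path: str | Path) -> None:
    """Write integer count matrices in JASPAR bracketed format (test fixtures)."""
    with open(path, "w") as fh:
        for mid, counts in pwms_counts.items():
            fh.write(f">{mid} {mid}\n")
            for b, row in zip(BASES, np.asarray(counts)):
                vals = " ".join(f"{int(v):6d}" for v in row)
                fh.write(f"{b}  [{vals} ]\n")


# ---------------------------------------------------------------------------
# TSV count matrices
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".samples.tsv")


def write_tsv_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV (first column ``feature_id``) plus a metadata sidecar."""
    path = Path(path)
    df = matrix.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    meta = matrix.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(_sidecar(path), sep="\t")


def read_tsv_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix and its ``<path>.samples.tsv`` sidecar."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate feature_ids")
    if df.size and (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    meta = pd.read_csv(_sidecar(path), sep="\t", index_col=0)
    return CountMatrix(df, meta)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a plain FASTA file into an ordered id -> sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
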