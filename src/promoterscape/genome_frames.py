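"""Gene-anchored coordinate frames for promoter analyses.

A gene's *promoter region* is the intergenic span from its translation
start codon to the coding boundary of the nearest upstream gene.  Positions
inside a promoter can be expressed in two reference frames:

``TSS``
    anchored on the transcription start site, so that the 5'UTR occupies
    positive positions and the region available for regulatory binding
    sites occupies negative positions;
``START_CODON``
    anchored on the first base of the coding sequence, the frame used by
    older positional surveys.

Frame coordinates are signed integers with **no position 0**: ``+1`` is the
anchor base itself and ``-1`` the base immediately upstream, so a site "115
bp upstream of the TSS" sits at frame position ``-115`` regardless of
strand.  Genomic coordinates are 1-based inclusive throughout; BED inputs
(0-based, half-open) are converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "GeneAnnotation",
    "SiteRecord",
    "FrameCoordinate",
    "PolymorphismEvent",
    "FrameGrid",
    "InputError",
    "UnusableGeneError",
    "read_annotations",
    "read_sites",
    "read_events",
    "to_frame",
    "from_frame",
    "promoter_coverage",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class UnusableGeneError(ValueError):
    """A gene lacks the anchor required by the requested frame."""


class Frame(str, Enum):
    TSS = "tss"
    START_CODON = "startcodon"


TATA_LABELS = ("containing", "less", "unknown")
EXPR_LABELS = ("high", "medium", "low", "unknown")


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic anchors and stratum labels for one gene.

    ``cds_start`` is the first coding base (the A of ATG in transcription
    direction); ``upstream_boundary`` the coding boundary of the nearest
    upstream gene.  The promoter region is the open interval between the
    two.  ``tss`` may be ``None`` for genes without a mapped transcription
    start; such genes are kept for start-codon-frame analyses only.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    upstream_boundary: int
    tss: int | None = None
    utr5_len: int | None = None
    tata: str = "unknown"
    expr_level: str = "unknown"
    bidirectional: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.promoter_len < 1:
            raise InputError(
                f"gene {self.gene_id}: promoter length "
                f"{self.promoter_len} < 1 (cds_start={self.cds_start}, "
                f"upstream_boundary={self.upstream_boundary})"
            )
        if self.tss is not None:
            d = (self.cds_start - self.tss) if self.strand == "+" else (self.tss - self.cds_start)
            if d < 0:
                raise InputError(
                    f"gene {self.gene_id}: TSS lies downstream of the start codon"
                )
            if d > self.promoter_len:
                raise InputError(
                    f"gene {self.gene_id}: TSS lies beyond the upstream boundary"
                )
            if self.utr5_len is None:
                object.__setattr__(self, "utr5_len", d)
            elif self.utr5_len != d:
                raise InputError(
                    f"gene {self.gene_id}: utr5_len={self.utr5_len} inconsistent "
                    f"with TSS-to-start-codon distance {d}"
                )

    # ---- geometry -------------------------------------------------------

    @property
    def has_tss(self) -> bool:
        return self.tss is not None

    @property
    def promoter_len(self) -> int:
        return abs(self.cds_start - self.upstream_boundary) - 1

    @property
    def promoter_interval(self) -> tuple[int, int]:
        """Genomic (start, end), 1-based inclusive, of the promoter region."""
        if self.strand == "+":
            return (self.upstream_boundary + 1, self.cds_start - 1)
        return (self.cds_start + 1, self.upstream_boundary - 1)

    @property
    def upstream_len(self) -> int:
        """Promoter bases upstream of the TSS (promoter minus 5'UTR)."""
        if self.tss is None:
            raise UnusableGeneError(f"gene {self.gene_id} has no TSS")
        return self.promoter_len - self.utr5_len

    def anchor(self, frame: Frame) -> int:
        if frame == Frame.TSS:
            if self.tss is None:
                raise UnusableGeneError(
                    f"gene {self.gene_id} has no TSS; unusable in the TSS frame"
                )
            return self.tss
        return self.cds_start

    def usable(self, frame: Frame) -> bool:
        return frame != Frame.TSS or self.tss is not None


@dataclass(frozen=True)
class SiteRecord:
    """One transcription-factor binding site assigned to a promoter."""

    tf: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(f"site {self.tf} {self.chrom}:{self.start}-{self.end}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FrameCoordinate:
    frame: Frame
    position: int

    def __post_init__(self):
        if self.position == 0:
            raise ValueError("frame coordinates have no position 0")


@dataclass(frozen=True)
class PolymorphismEvent:
    """A segregating SNP (start == end) or deletion interval."""

    kind: str  # "SNP" | "deletion"
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise InputError("polymorphism event with start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# frame arithmetic
# ---------------------------------------------------------------------------

def _offset_to_frame(off):
    """Signed offset (0 = anchor) -> no-zero frame coordinate."""
    off = np.asarray(off)
    return off + (off >= 0)


def _frame_to_offset(pos):
    pos = np.asarray(pos)
    return pos - (pos > 0)


def to_frame(site_or_position, gene: GeneAnnotation, frame: Frame) -> FrameCoordinate:
    """Map a genomic position (or a site's midpoint) into a reference frame.

    Upstream positions are negative; the anchor base is ``+1``.  For a
    ``SiteRecord`` the interval midpoint is used, with even-length ties
    broken to the upstream (anchor-distal) central base so that a 10-bp
    site at genomic 881-890 on a plus-strand gene with TSS 1000 maps to
    ``-115``.
    """
    if isinstance(site_or_position, SiteRecord):
        pos = site_midpoint(site_or_position, gene.strand)
    else:
        pos = int(site_or_position)
    a = gene.anchor(frame)
    off = (pos - a) if gene.strand == "+" else (a - pos)
    return FrameCoordinate(frame, int(_offset_to_frame(off)))


def from_frame(position: int, gene: GeneAnnotation, frame: Frame) -> int:
    """Inverse of :func:`to_frame` for a single frame position."""
    if position == 0:
        raise ValueError("frame coordinates have no position 0")
    a = gene.anchor(frame)
    off = int(_frame_to_offset(position))
    return a + off if gene.strand == "+" else a - off


def site_midpoint(site: SiteRecord, strand: str) -> int:
    """Genomic midpoint of a site; even lengths round to the upstream base."""
    h = (site.length - 1) // 2
    return site.start + h if strand == "+" else site.end - h


# ---------------------------------------------------------------------------
# frame grid: a contiguous integer indexing of no-zero frame coordinates
# ---------------------------------------------------------------------------

def _u(x):
    """Linearize no-zero frame coordinates: ...,-2,-1,+1,+2,... -> ...,-2,-1,0,1,..."""
    x = np.asarray(x)
    return x - (x > 0)


def _x(u):
    u = np.asarray(u)
    return u + (u >= 0)


class FrameGrid:
    """A contiguous range of frame coordinates with array indexing.

    Internally positions are linearized (``u = x - 1`` for ``x > 0``) so
    that ``-1`` and ``+1`` are adjacent and moving averages slide smoothly
    across the anchor.
    """

    def __init__(self, lo: int, hi: int):
        if lo == 0 or hi == 0:
            raise ValueError("frame coordinates have no position 0")
        if lo >= hi:
            raise ValueError("grid requires lo < hi")
        self.lo, self.hi = int(lo), int(hi)
        self.u_lo = int(_u(lo))
        self.u_hi = int(_u(hi))
        self.size = self.u_hi - self.u_lo + 1
        self.positions = _x(np.arange(self.u_lo, self.u_hi + 1))

    def index(self, x):
        """Array index of frame coordinate(s) x (may fall outside the grid)."""
        return _u(x) - self.u_lo

    def contains(self, x):
        u = _u(x)
        return (u >= self.u_lo) & (u <= self.u_hi)

    def accumulate_intervals(self, u_lo, u_hi, weights=None) -> np.ndarray:
        """Sum of weighted indicator functions of u-intervals, clipped to the grid."""
        u_lo = np.asarray(u_lo, dtype=np.int64)
        u_hi = np.asarray(u_hi, dtype=np.int64)
        w = np.ones(u_lo.shape, dtype=float) if weights is None else np.asarray(weights, dtype=float)
        a = np.clip(u_lo - self.u_lo, 0, self.size)
        b = np.clip(u_hi - self.u_lo + 1, 0, self.size)
        keep = b > a
        diff = np.zeros(self.size + 1)
        np.add.at(diff, a[keep], w[keep])
        np.add.at(diff, b[keep], -w[keep])
        return np.cumsum(diff[:-1])


def gene_cover_u(gene: GeneAnnotation, frame: Frame) -> tuple[int, int]:
    """Linearized frame interval covered by the gene's promoter (incl. 5'UTR).

    In the TSS frame the promoter occupies ``-upstream_len .. -1`` plus the
    5'UTR at ``+1 .. +utr5_len``; linearized these are one contiguous run.
    In the start-codon frame the whole promoter is upstream.
    """
    if frame == Frame.TSS:
        return (-gene.upstream_len, gene.utr5_len - 1)
    return (-gene.promoter_len, -1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("gene_id", "chrom", "strand", "tss", "cds_start", "upstream_boundary")


def read_annotations(path) -> list[GeneAnnotation]:
    """Load gene annotations from TSV (or GFF3) and derive geometry flags.

    Rows whose TSS lies downstream of the start codon (or beyond the
    upstream boundary) are rejected with a warning.  The bidirectional flag
    is set for reciprocal divergent pairs: genes *a*, *b* on the same
    chromosome with opposite strands where each lists the other's coding
    start as its upstream boundary.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff-version") or path.suffix.lower() in (".gff", ".gff3"):
        rows = _gff3_rows(path)
    else:
        rows = _tsv_rows(path)

    genes: list[GeneAnnotation] = []
    for lineno, row in rows:
        try:
            gene = GeneAnnotation(**row)
        except InputError as exc:
            if "TSS lies" in str(exc):
                log.warning("line %d: %s; record rejected", lineno, exc)
                continue
            raise InputError(f"line {lineno}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise InputError(f"malformed row at line {lineno}: {exc}") from exc
        genes.append(gene)

    genes = _flag_bidirectional(genes)
    n_no_tss = sum(not g.has_tss for g in genes)
    if n_no_tss:
        log.info("%d/%d genes lack a TSS (start-codon frame only)", n_no_tss, len(genes))
    return genes


def _tsv_rows(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    out = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        rec = rec._asdict()
        try:
            tss = rec.get("tss")
            tss = None if tss is None or pd.isna(tss) or str(tss) in ("", "NA", ".") else int(tss)
            utr = rec.get("utr5_len")
            utr = None if utr is None or pd.isna(utr) or str(utr) in ("", "NA", ".") else int(utr)
            row = dict(
                gene_id=str(rec["gene_id"]),
                chrom=str(rec["chrom"]),
                strand=str(rec["strand"]),
                tss=tss,
                cds_start=int(rec["cds_start"]),
                upstream_boundary=int(rec["upstream_boundary"]),
                utr5_len=utr,
                tata=str(rec.get("tata", "unknown") or "unknown"),
                expr_level=str(rec.get("expr_level", "unknown") or "unknown"),
            )
        except (KeyError, ValueError) as exc:
            raise InputError(f"malformed row at line {i}: {exc}") from exc
        if row["tata"] not in TATA_LABELS or row["expr_level"] not in EXPR_LABELS:
            raise InputError(f"malformed row at line {i}: bad tata/expr_level label")
        out.append((i, row))
    return out


def _gff3_rows(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise InputError(f"malformed GFF3 row at line {lineno}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            kv = dict(
                item.split("=", 1) for item in attrs.strip(";").split(";") if "=" in item
            )
            try:
                cds_start = int(start) if strand == "+" else int(end)
                row = dict(
                    gene_id=kv.get("ID", f"gene_{lineno}"),
                    chrom=chrom,
                    strand=strand,
                    tss=int(kv["tss"]) if kv.get("tss", ".") not in (".", "") else None,
                    cds_start=cds_start,
                    upstream_boundary=int(kv["upstream_boundary"]),
                    utr5_len=int(kv["utr5_len"]) if "utr5_len" in kv else None,
                    tata=kv.get("tata", "unknown"),
                    expr_level=kv.get("expr_level", "unknown"),
                )
            except (KeyError, ValueError) as exc:
                raise InputError(f"malformed GFF3 row at line {lineno}: {exc}") from exc
            out.append((lineno, row))
    return out


def _flag_bidirectional(genes: list[GeneAnnotation]) -> list[GeneAnnotation]:
    by_key = {(g.chrom, g.cds_start): g for g in genes}
    out = []
    for g in genes:
        partner = by_key.get((g.chrom, g.upstream_boundary))
        bidir = (
            partner is not None
            and partner.strand != g.strand
            and partner.upstream_boundary == g.cds_start
        )
        out.append(replace(g, bidirectional=bidir) if bidir != g.bidirectional else g)
    return out


def read_sites(path, genes: Sequence[GeneAnnotation]) -> tuple[list[SiteRecord], int]:
    """Read a BED site table and assign each site to containing promoters.

    BED name field carries the TF name.  A site is assigned to every gene
    whose promoter region fully contains it (both genes of a shared
    bidirectional promoter may claim the same site); sites contained in no
    promoter are rejected and counted.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = g.promoter_interval
        trees.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g)
    sites: list[SiteRecord] = []
    rejected = 0
    for rec in df.itertuples(index=False):
        chrom = str(rec[0])
        start = int(rec[1]) + 1  # BED 0-based -> 1-based
        end = int(rec[2])
        tf = str(rec[3]) if df.shape[1] > 3 else "NA"
        hits = [
            iv.data
            for iv in trees.get(chrom, IntervalTree()).overlap(start, end + 1)
            if iv.begin <= start and end < iv.end
        ]
        if not hits:
            rejected += 1
            continue
        for g in hits:
            sites.append(SiteRecord(tf=tf, chrom=chrom, start=start, end=end, gene_id=g.gene_id))
    if rejected:
        log.info("%d sites fell outside all promoter regions and were rejected", rejected)
    return sites, rejected


def read_events(path, kind: str) -> list[PolymorphismEvent]:
    """Read SNP or deletion intervals from BED (0-based half-open on disk)."""
    if kind not in ("SNP", "deletion"):
        raise InputError("kind must be 'SNP' or 'deletion'")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise InputError(f"{path}: BED needs at least 3 columns")
    return [
        PolymorphismEvent(kind=kind, chrom=str(r[0]), start=int(r[1]) + 1, end=int(r[2]))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def promoter_coverage(
    genes: Sequence[GeneAnnotation],
    frame: Frame,
    frame_range: tuple[int, int],
    exclude_bidirectional: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position promoter sequence counts r(x) on a frame range.

    r(x) is the number of genes whose promoter region (5'UTR included for
    positive TSS-frame positions) contains frame position x — the
    denominator that turns raw site counts into densities.
    """
    usable = [g for g in genes if g.usable(frame) and not (exclude_bidirectional and g.bidirectional)]
    n_skipped = len(genes) - len(usable)
    if n_skipped:
        log.info("%d genes unusable in frame %s excluded from coverage", n_skipped, frame.value)
    if not usable:
        raise InputError("no usable genes for coverage computation")
    grid = FrameGrid(*frame_range)
    cov = np.array([gene_cover_u(g, frame) for g in usable], dtype=np.int64)
    r = grid.accumulate_intervals(cov[:, 0], cov[:, 1])
    return grid.positions, r
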