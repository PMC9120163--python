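"""Genomic interval primitives, annotation and alignment I/O, region classification.

All coordinates are 0-based, half-open throughout the package; GTF input
(1-based, inclusive) is converted at the boundary.  "Overlap" always means
at least one shared base under half-open arithmetic, so touching intervals
([0,10) and [10,20)) do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: region classes returned by :func:`classify_position`, in precedence order
REGION_CLASSES = ("cds", "5utr", "3utr", "intron", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Transcript:
    """One transcript: an ordered, disjoint exon chain with an optional CDS span."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons not sorted/disjoint at {a}..{b}"
                )
        if self.cds is not None:
            if not (self.span.start <= self.cds.start < self.cds.end <= self.span.end):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")
            if not any(e.contains_point(self.cds.start) for e in self.exons) or not any(
                e.contains_point(self.cds.end - 1) for e in self.exons
            ):
                raise ValueError(f"{self.transcript_id}: CDS boundary not exonic")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(start, end) coordinate pairs of the introns."""
        return tuple((i.start, i.end) for i in self.introns)

    def _exonic_split(self) -> tuple[list, list, list]:
        """Exonic pieces 5' of CDS, inside CDS, 3' of CDS (genomic order)."""
        if self.cds is None:
            return [], list(self.exons), []
        left, mid, right = [], [], []
        for e in self.exons:
            pieces = [
                (e.start, min(e.end, self.cds.start)),
                (max(e.start, self.cds.start), min(e.end, self.cds.end)),
                (max(e.start, self.cds.end), e.end),
            ]
            for (s, t), bucket in zip(pieces, (left, mid, right)):
                if s < t:
                    bucket.append(GenomicInterval(self.chrom, s, t, self.strand))
        return left, mid, right

    @property
    def cds_intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(self._exonic_split()[1])

    @property
    def utr5_intervals(self) -> tuple[GenomicInterval, ...]:
        """Exonic intervals 5' of the CDS (strand-aware)."""
        left, _, right = self._exonic_split()
        return tuple(left if self.strand != "-" else right)

    @property
    def utr3_intervals(self) -> tuple[GenomicInterval, ...]:
        left, _, right = self._exonic_split()
        return tuple(right if self.strand != "-" else left)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ValueError(f"{self.gene_id}: transcripts on mixed chroms")
        if len({t.strand for t in self.transcripts}) != 1:
            raise ValueError(f"{self.gene_id}: transcripts on mixed strands")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exon_union(self) -> tuple[GenomicInterval, ...]:
        return tuple(merge_intervals([e for t in self.transcripts for e in t.exons]))

    @property
    def exon_union_length(self) -> int:
        return sum(e.length for e in self.exon_union)

    def region_union(self, region: str) -> tuple[GenomicInterval, ...]:
        """Merged exonic intervals of one region class over all transcripts."""
        attr = {"cds": "cds_intervals", "5utr": "utr5_intervals", "3utr": "utr3_intervals"}[
            region
        ]
        xs = [iv for t in self.transcripts for iv in getattr(t, attr)]
        return tuple(merge_intervals(xs)) if xs else ()

    @property
    def annotated_introns(self) -> dict[tuple[int, int], int]:
        """Intron (start, end) -> index of the first transcript carrying it."""
        out: dict[tuple[int, int], int] = {}
        for i, t in enumerate(self.transcripts):
            for j in t.junctions:
                out.setdefault(j, i)
        return out

    @property
    def annotated_exons(self) -> tuple[GenomicInterval, ...]:
        seen: dict[tuple[int, int], GenomicInterval] = {}
        for t in self.transcripts:
            for e in t.exons:
                seen.setdefault((e.start, e.end), e)
        return tuple(seen[k] for k in sorted(seen))


@dataclass(frozen=True)
class AlignedRead:
    """An aligned read as an ordered list of gapless blocks.

    Gaps between consecutive blocks are the read's splice junctions;
    a single-block read is unspliced.
    """

    read_id: str
    sample_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.read_id}: blocks not sorted/disjoint")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        )


class GtfParseError(ValueError):
    pass


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    out = {}
    for piece in text.strip().strip(";").split(";"):
        piece = piece.strip()
        if not piece:
            continue
        key, _, value = piece.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon and CDS features from a GTF file into gene models.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exon records lacking a ``transcript_id`` are skipped with a warning;
    malformed lines raise :class:`GtfParseError` naming the line number.
    Genes are returned sorted by (chrom, span start, gene_id).
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    cds: dict[tuple[str, str], list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: bad coordinates") from exc
            if not (0 <= start < end):
                raise GtfParseError(f"{path}:{lineno}: empty/negative interval")
            attrs = _parse_gtf_attributes(attrs_s)
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if gid is None:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id")
            if tid is None:
                logger.warning("%s:%d: %s without transcript_id, skipped", path, lineno, feature)
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            (exons if feature == "exon" else cds).setdefault((gid, tid), []).append(iv)

    by_gene: dict[str, list[Transcript]] = {}
    for (gid, tid), ivs in exons.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        cds_span = None
        if (gid, tid) in cds:
            cs = cds[(gid, tid)]
            cds_span = GenomicInterval(
                ivs[0].chrom,
                min(c.start for c in cs),
                max(c.end for c in cs),
                ivs[0].strand,
            )
        by_gene.setdefault(gid, []).append(
            Transcript(tid, gid, tuple(ivs), cds_span)
        )
    genes = [
        GeneModel(gid, tuple(sorted(ts, key=lambda t: t.transcript_id)))
        for gid, ts in by_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, header: Optional[str] = None) -> None:
    """Write gene models back to GTF (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for g in genes:
            for t in g.transcripts:
                for e in t.exons:
                    _write_gtf_feature(fh, g, t, "exon", e)
                if t.cds is not None:
                    for c in t.cds_intervals:
                        _write_gtf_feature(fh, g, t, "CDS", c)


def _write_gtf_feature(fh, g: GeneModel, t: Transcript, feature: str, iv: GenomicInterval) -> None:
    attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
    fh.write(
        f"{iv.chrom}\tspliceclip\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
    )


def _blocks_from_cigar(chrom: str, strand: str, pos: int, cigartuples) -> tuple[GenomicInterval, ...]:
    """Reference blocks from CIGAR; N gaps split blocks, D does not."""
    blocks: list[GenomicInterval] = []
    cur = pos
    block_start = pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference within a block
            cur += length
        elif op == 3:  # N: splice gap
            if cur > block_start:
                blocks.append(GenomicInterval(chrom, block_start, cur, strand))
            cur += length
            block_start = cur
        # I, S, H, P consume no reference
    if cur > block_start:
        blocks.append(GenomicInterval(chrom, block_start, cur, strand))
    return tuple(blocks)


def _read_sam(path: str | Path, sample_id: str) -> Iterator[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            blocks = _blocks_from_cigar(
                rec.reference_name, strand, rec.reference_start, rec.cigartuples or []
            )
            if blocks:
                yield AlignedRead(rec.query_name, sample_id, rec.reference_name, strand, blocks)


def _read_bed12(path: str | Path, sample_id: str) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            yield AlignedRead(name, sample_id, chrom, strand, blocks)


def read_alignments(
    path: str | Path, dialect: str = "sam", sample_id: Optional[str] = None
) -> Iterator[AlignedRead]:
    """Stream aligned reads from SAM or BED12.

    For SAM, secondary/supplementary/unmapped records are excluded so that
    only uniquely-placed alignments contribute; BED12 input is assumed to be
    pre-filtered to unique alignments.
    """
    sample_id = sample_id or Path(path).stem
    if dialect == "sam":
        return _read_sam(path, sample_id)
    if dialect == "bed12":
        return _read_bed12(path, sample_id)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_bed12(
    reads: Iterable[AlignedRead], path: str | Path, header: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for r in reads:
            start, end = r.span.start, r.span.end
            sizes = ",".join(str(b.length) for b in r.blocks)
            offsets = ",".join(str(b.start - start) for b in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}\t{start}\t{end}\t0\t"
                f"{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence] = None,
    extra: Optional[Sequence[Sequence]] = None,
    header: Optional[str] = None,
) -> None:
    intervals = list(intervals)
    names = names or [f"iv{i}" for i in range(len(intervals))]
    scores = scores if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for i, iv in enumerate(intervals):
            row = [iv.chrom, iv.start, iv.end, names[i], scores[i], iv.strand]
            if extra is not None:
                row.extend(extra[i])
            fh.write("\t".join(str(x) for x in row) + "\n")


def merge_intervals(xs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals sharing >= 1 base; touching intervals stay separate.

    All inputs must be on one chromosome.  Output is sorted, pairwise
    disjoint and covers exactly the union of the inputs.  Strand is kept if
    uniform, otherwise '.'.
    """
    xs = list(xs)
    if not xs:
        return []
    if len({x.chrom for x in xs}) != 1:
        raise ValueError("merge_intervals: mixed chromosomes")
    strands = {x.strand for x in xs}
    strand = strands.pop() if len(strands) == 1 else "."
    xs.sort(key=lambda x: (x.start, x.end))
    out: list[list[int]] = [[xs[0].start, xs[0].end]]
    for x in xs[1:]:
        if x.start < out[-1][1]:  # >=1 shared base
            out[-1][1] = max(out[-1][1], x.end)
        else:
            out.append([x.start, x.end])
    return [GenomicInterval(xs[0].chrom, s, e, strand) for s, e in out]


class GeneIndex:
    """Interval index over gene spans for point/interval lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            sp = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(sp.start, sp.end, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def containing_point(self, chrom: str, pos: int, strand: Optional[str] = None) -> list[GeneModel]:
        hits = self.overlapping(chrom, pos, pos + 1)
        if strand in ("+", "-"):
            hits = [g for g in hits if g.strand == strand]
        return hits


def _classify_in_gene(g: GeneModel, pos: int) -> str:
    for region in ("cds", "5utr", "3utr"):
        if any(iv.contains_point(pos) for iv in g.region_union(region)):
            return region
    # exonic but outside any annotated CDS/UTR partition (e.g. CDS-less
    # transcript): count as cds, the coding-gene default
    if any(e.contains_point(pos) for e in g.exon_union):
        return "cds"
    return "intron"


def classify_position(genes: Iterable[GeneModel] | GeneIndex, pos: GenomicInterval) -> str:
    """Classify a position's midpoint as 5utr/cds/3utr/intron/intergenic.

    When the position falls in several genes, the strand-matching gene with
    the smallest span wins; within a gene, region precedence is
    cds > 5utr > 3utr > intron.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    point = pos.midpoint
    hits = index.containing_point(pos.chrom, point, pos.strand if pos.strand != "." else None)
    if not hits and pos.strand != ".":
        hits = []
    if not hits:
        # fall back to any-strand lookup only for unstranded queries
        if pos.strand == ".":
            hits = index.containing_point(pos.chrom, point)
        if not hits:
            return "intergenic"
    g = min(hits, key=lambda g: (g.span.length, g.gene_id))
    return _classify_in_gene(g, point)
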