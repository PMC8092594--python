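"""Reading and writing of the genomic file formats the pipeline touches.

All in-memory coordinates are 0-based half-open (BED convention); GFF3's
1-based inclusive coordinates are converted at the I/O boundary and nowhere
else.  Only ``gene``, ``mRNA`` and ``CDS`` features of a GFF3 file are
consulted — the analysis needs a gene's transcribed span and coding span,
nothing more.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO
from urllib.parse import unquote

__all__ = [
    "GenomicInterval",
    "ScoredPeak",
    "GeneModel",
    "GeneAnnotation",
    "AnnotationError",
    "PeakFormatError",
    "read_gff3",
    "write_gff3",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_list",
    "write_gene_list",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class PeakFormatError(ValueError):
    """Malformed narrowPeak input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


#: sentinel for a peak whose summit offset is not reported (narrowPeak -1)
SUMMIT_UNKNOWN = None


@dataclass(frozen=True)
class ScoredPeak:
    """One narrowPeak record: an interval with an FDR-like q-score.

    ``qscore`` is on the -log10 scale of narrowPeak column 9, so the filter
    "FDR < 0.001" reads ``qscore > 3``.  ``summit_offset`` is measured in bp
    from ``interval.start``; ``None`` means unreported.
    """

    interval: GenomicInterval
    peak_id: str
    qscore: float
    summit_offset: int | None = SUMMIT_UNKNOWN

    def __post_init__(self) -> None:
        if self.qscore < 0:
            raise ValueError(f"qscore must be >= 0, got {self.qscore}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )

    @property
    def fdr(self) -> float:
        """q-score converted back to an FDR probability (10**-qscore)."""
        return 10.0 ** (-self.qscore)


@dataclass(frozen=True)
class GeneModel:
    """A gene: transcribed span plus the coding span contained in it."""

    gene_id: str
    chrom: str
    strand: str
    tx_span: GenomicInterval
    cds_span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_span.contains(self.cds_span):
            raise AnnotationError(
                f"gene {self.gene_id}: CDS span {self.cds_span} not contained "
                f"in transcript span {self.tx_span}"
            )


@dataclass
class GeneAnnotation:
    """A set of gene models plus chromosome lengths."""

    genes: list[GeneModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene ID {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise AnnotationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom!r}"
                )
            if g.tx_span.end > size:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.tx_span.end} > {size})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def read_gff3(source: TextIO | str) -> GeneAnnotation:
    """Parse a GFF3 stream into a :class:`GeneAnnotation`.

    Gene features must carry an ``ID`` attribute; CDS features are attached
    to a gene directly or through an intermediate mRNA.  Chromosome sizes
    come from ``##sequence-region`` pragmas.  GFF3 coordinates (1-based
    inclusive) are converted to 0-based half-open.  A gene's coding span is
    the min CDS start to max CDS end over its CDS features; genes without
    CDS inherit their transcribed span as coding span.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    chrom_sizes: dict[str, int] = {}
    # gene_id -> (chrom, strand, start, end)
    gene_rows: dict[str, tuple[str, str, int, int]] = {}
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}
    # parent id -> [start, end] extent of CDS in 0-based half-open coords
    cds_extent: dict[str, list[int]] = {}

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) != 4:
                raise AnnotationError(
                    f"line {lineno}: malformed ##sequence-region pragma"
                )
            chrom_sizes[parts[1]] = int(parts[3])
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        chrom, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
        if ftype not in ("gene", "mRNA", "CDS"):
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from exc
        if start1 < 1 or end1 < start1:
            raise AnnotationError(
                f"line {lineno}: invalid GFF3 span {start1}..{end1}"
            )
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        attrs = _parse_attributes(col9)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise AnnotationError(f"line {lineno}: gene lacks ID attribute")
            if gid in gene_rows:
                raise AnnotationError(f"line {lineno}: duplicate gene ID {gid!r}")
            gene_rows[gid] = (chrom, strand, start, end)
            gene_order.append(gid)
        elif ftype == "mRNA":
            mid, parent = attrs.get("ID"), attrs.get("Parent")
            if mid is not None and parent is not None:
                mrna_parent[mid] = parent
        else:  # CDS
            parent = attrs.get("Parent")
            if parent is None:
                raise AnnotationError(f"line {lineno}: CDS lacks Parent attribute")
            for p in parent.split(","):
                ext = cds_extent.setdefault(p, [start, end])
                ext[0] = min(ext[0], start)
                ext[1] = max(ext[1], end)

    # fold mRNA-level CDS extents up to their genes
    gene_cds: dict[str, list[int]] = {}
    for pid, (s, e) in cds_extent.items():
        gid = mrna_parent.get(pid, pid)
        ext = gene_cds.setdefault(gid, [s, e])
        ext[0] = min(ext[0], s)
        ext[1] = max(ext[1], e)

    genes = []
    for gid in gene_order:
        chrom, strand, start, end = gene_rows[gid]
        tx = GenomicInterval(chrom, start, end)
        if gid in gene_cds:
            cs, ce = gene_cds[gid]
            if cs < start or ce > end:
                raise AnnotationError(
                    f"gene {gid}: CDS [{cs}, {ce}) outside gene span "
                    f"[{start}, {end})"
                )
            cds = GenomicInterval(chrom, cs, ce)
        else:
            cds = tx
        genes.append(GeneModel(gid, chrom, strand, tx, cds))

    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def write_gff3(annotation: GeneAnnotation, sink: TextIO) -> None:
    """Write an annotation as GFF3 (gene + CDS features, sequence-region pragmas)."""
    sink.write("##gff-version 3\n")
    for chrom in sorted(annotation.chrom_sizes):
        sink.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
    for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.tx_span.start, g.gene_id)):
        tx, cds = g.tx_span, g.cds_span
        sink.write(
            f"{g.chrom}\ttargetcall\tgene\t{tx.start + 1}\t{tx.end}\t.\t"
            f"{g.strand}\t.\tID={g.gene_id}\n"
        )
        sink.write(
            f"{g.chrom}\ttargetcall\tCDS\t{cds.start + 1}\t{cds.end}\t.\t"
            f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
        )


# ---------------------------------------------------------------------------
# narrowPeak (BED6+4)
# ---------------------------------------------------------------------------

def read_narrowpeak(source: TextIO | str) -> list[ScoredPeak]:
    """Parse narrowPeak (BED6+4) lines into :class:`ScoredPeak` records.

    Column 9 (qValue, -log10) becomes ``qscore``; a qValue of -1 (value not
    available) is an error because the FDR filter cannot read it.  Column 10
    (summit offset) of -1 maps to "unknown".
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    peaks: list[ScoredPeak] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 10:
            raise PeakFormatError(
                f"line {lineno}: narrowPeak needs 10 columns, got {len(cols)}"
            )
        chrom, start_s, end_s, name = cols[0], cols[1], cols[2], cols[3]
        try:
            start, end = int(start_s), int(end_s)
            qvalue = float(cols[8])
            summit = int(cols[9])
        except ValueError as exc:
            raise PeakFormatError(f"line {lineno}: {exc}") from exc
        if end <= start:
            raise PeakFormatError(
                f"line {lineno}: end ({end}) must exceed start ({start})"
            )
        if qvalue < 0:
            raise PeakFormatError(
                f"line {lineno}: qValue unavailable (-1); the FDR filter "
                "requires scored peaks"
            )
        peaks.append(
            ScoredPeak(
                interval=GenomicInterval(chrom, start, end),
                peak_id=name,
                qscore=qvalue,
                summit_offset=None if summit == -1 else summit,
            )
        )
    return peaks


def write_narrowpeak(peaks: Iterable[ScoredPeak], sink: TextIO) -> None:
    """Write peaks as narrowPeak, sorted by (chrom, start, end, id).

    signalValue and pValue columns are not tracked by the pipeline and are
    written as 0.
    """
    ordered = sorted(
        peaks,
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.peak_id),
    )
    for p in ordered:
        summit = -1 if p.summit_offset is None else p.summit_offset
        sink.write(
            f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
            f"{p.peak_id}\t0\t.\t0\t0\t{p.qscore:g}\t{summit}\n"
        )


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def read_gene_list(source: TextIO | str) -> set[str]:
    """Read a one-ID-per-line gene list; blank lines and '#' comments skipped."""
    if isinstance(source, str):
        source = io.StringIO(source)
    ids = set()
    for raw in source:
        line = raw.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def write_gene_list(gene_ids: Iterable[str], sink: TextIO) -> None:
    for gid in sorted(gene_ids):
        sink.write(gid + "\n")
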