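"""Peak-to-gene target assignment.

A consensus region is associated with a gene when the region's center lies
within a strand-aware window extending 3 kb upstream to 1.5 kb downstream
of the gene's coding sequence, and no other gene's transcribed span
intervenes between the region center and the near edge of that coding
sequence.  A region may be assigned to more than one gene (divergent
promoters); the intervening-gene veto is evaluated per candidate gene.

Geometry conventions
--------------------
Offsets are signed and strand-aware: negative upstream of the anchor span's
5' edge (promoter side), 0-based within the span measured from its 5' edge,
and positive past the 3' edge (downstream side, first base past the span is
+1).  Window boundaries are inclusive: a center exactly ``upstream_bp``
before the anchor (offset -3000 by default) still qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .annotation_io import GeneAnnotation, GeneModel, GenomicInterval
from .consensus import ConsensusRegion

__all__ = [
    "GeneWindow",
    "TargetAssignment",
    "classify_offset",
    "build_windows",
    "assign_region",
    "assign_regions",
    "target_gene_set",
]

Zone = Literal["promoter", "transcribed", "downstream"]
Anchor = Literal["coding", "transcript"]

DEFAULT_UPSTREAM_BP = 3000
DEFAULT_DOWNSTREAM_BP = 1500


@dataclass(frozen=True)
class GeneWindow:
    """Strand-aware search window around one gene's anchor span."""

    gene_id: str
    interval: GenomicInterval
    anchor: Anchor
    upstream_bp: int = DEFAULT_UPSTREAM_BP
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP


@dataclass(frozen=True)
class TargetAssignment:
    """One (region, gene) association with its zone and signed offset."""

    region_id: str
    gene_id: str
    zone: Zone
    offset: int


def _anchor_span(gene: GeneModel, anchor: Anchor) -> GenomicInterval:
    if anchor == "coding":
        return gene.cds_span
    if anchor == "transcript":
        return gene.tx_span
    raise ValueError(f"anchor must be 'coding' or 'transcript', got {anchor!r}")


def classify_offset(
    center: int,
    span: GenomicInterval,
    strand: str,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
) -> tuple[str, int]:
    """Classify a position against an anchor span; returns (zone, offset).

    zone is one of promoter / transcribed / downstream / outside; the
    offset satisfies -upstream_bp <= offset < 0 for promoter,
    0 <= offset < len(span) for transcribed, and
    0 < offset <= downstream_bp for downstream.
    """
    if strand == "+":
        if center < span.start:
            offset = center - span.start
            return ("promoter" if offset >= -upstream_bp else "outside", offset)
        if center < span.end:
            return "transcribed", center - span.start
        offset = center - span.end + 1
        return ("downstream" if offset <= downstream_bp else "outside", offset)
    if strand == "-":
        if center >= span.end:
            offset = -(center - span.end + 1)
            return ("promoter" if offset >= -upstream_bp else "outside", offset)
        if center >= span.start:
            return "transcribed", (span.end - 1) - center
        offset = span.start - center
        return ("downstream" if offset <= downstream_bp else "outside", offset)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def build_windows(
    annotation: GeneAnnotation,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    anchor: Anchor = "coding",
) -> list[GeneWindow]:
    """One search window per gene, extended strand-aware and clipped.

    For a + strand gene the window is [anchor.start - upstream_bp,
    anchor.end + downstream_bp); for - strand the extensions swap sides.
    Windows are clipped to [0, chromosome length).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extensions must be non-negative")
    windows = []
    for gene in annotation.genes:
        size = annotation.chrom_sizes.get(gene.chrom)
        if size is None:
            raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
        span = _anchor_span(gene, anchor)
        if gene.strand == "+":
            lo, hi = span.start - upstream_bp, span.end + downstream_bp
        else:
            lo, hi = span.start - downstream_bp, span.end + upstream_bp
        windows.append(
            GeneWindow(
                gene_id=gene.gene_id,
                interval=GenomicInterval(gene.chrom, max(0, lo), min(size, hi)),
                anchor=anchor,
                upstream_bp=upstream_bp,
                downstream_bp=downstream_bp,
            )
        )
    return windows


def _has_intervening_gene(
    center: int,
    span: GenomicInterval,
    candidate_id: str,
    chrom_genes: Sequence[GeneModel],
) -> bool:
    """True if another gene's transcribed span overlaps the open gap
    between the position and the near edge of the candidate's anchor span."""
    if span.start <= center < span.end:
        return False
    if center < span.start:
        gap_lo, gap_hi = center + 1, span.start
    else:
        gap_lo, gap_hi = span.end, center
    if gap_lo >= gap_hi:
        return False
    for g in chrom_genes:
        if g.gene_id == candidate_id:
            continue
        if g.tx_span.start < gap_hi and g.tx_span.end > gap_lo:
            return True
    return False


class _AssignmentIndex:
    """Precomputed per-chromosome lookups shared across many regions."""

    def __init__(self, windows: Sequence[GeneWindow], annotation: GeneAnnotation):
        self.genes = annotation.by_id()
        self.chrom_genes: dict[str, list[GeneModel]] = {}
        for g in annotation.genes:
            self.chrom_genes.setdefault(g.chrom, []).append(g)
        self.chrom_windows: dict[str, list[GeneWindow]] = {}
        for w in windows:
            self.chrom_windows.setdefault(w.interval.chrom, []).append(w)

    def assign(self, region_id: str, chrom: str, center: int) -> list[TargetAssignment]:
        out = []
        for w in self.chrom_windows.get(chrom, []):
            iv = w.interval
            if not (iv.start <= center < iv.end):
                continue
            gene = self.genes[w.gene_id]
            span = _anchor_span(gene, w.anchor)
            if _has_intervening_gene(
                center, span, gene.gene_id, self.chrom_genes[chrom]
            ):
                continue
            zone, offset = classify_offset(
                center, span, gene.strand, w.upstream_bp, w.downstream_bp
            )
            # window membership guarantees an in-zone classification
            assert zone != "outside"
            out.append(
                TargetAssignment(
                    region_id=region_id, gene_id=gene.gene_id,
                    zone=zone, offset=offset,
                )
            )
        return out


def assign_region(
    region: ConsensusRegion,
    windows: Sequence[GeneWindow],
    annotation: GeneAnnotation,
) -> list[TargetAssignment]:
    """All genes the region is assigned to under the window and
    intervening-gene rules; possibly empty, possibly several."""
    index = _AssignmentIndex(windows, annotation)
    return index.assign(region.region_id, region.interval.chrom, region.center)


def assign_regions(
    regions: Sequence[ConsensusRegion],
    annotation: GeneAnnotation,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    anchor: Anchor = "coding",
) -> list[TargetAssignment]:
    """Assign every region against windows built from the annotation."""
    windows = build_windows(annotation, upstream_bp, downstream_bp, anchor)
    index = _AssignmentIndex(windows, annotation)
    out: list[TargetAssignment] = []
    for region in regions:
        out.extend(index.assign(region.region_id, region.interval.chrom, region.center))
    return out


def target_gene_set(assignments: Sequence[TargetAssignment]) -> list[str]:
    """Deduplicated, sorted gene ids appearing in the assignments."""
    return sorted({a.gene_id for a in assignments})
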