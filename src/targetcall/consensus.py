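"""Replicate-consensus peak filtering.

A consensus region is a maximal genomic interval covered by at least one
FDR-qualifying peak in *every* treatment replicate and overlapped by no
qualifying control peak.  Coverage is evaluated per base (the common
intersection of all replicates, not pairwise chaining), so with three
replicate peaks [100,200), [150,250) and [120,220) the consensus region is
[150,200).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

from .annotation_io import GenomicInterval, ScoredPeak

__all__ = [
    "ConsensusRegion",
    "filter_by_fdr",
    "intersect_replicates",
    "exclude_control",
    "consensus_regions",
]


@dataclass(frozen=True)
class ConsensusRegion:
    """Maximal interval supported by every treatment replicate.

    ``support`` maps a replicate label ("rep1", "rep2", ...) to the id of
    the contributing peak in that replicate (the overlapping peak with the
    leftmost start, ties broken by lexicographic peak id).
    """

    interval: GenomicInterval
    region_id: str
    support: tuple[tuple[str, str], ...]

    @property
    def center(self) -> int:
        """Midpoint of the interval, rounded down."""
        return (self.interval.start + self.interval.end) // 2

    @property
    def support_dict(self) -> dict[str, str]:
        return dict(self.support)


def filter_by_fdr(
    peaks: Sequence[ScoredPeak], fdr_threshold: float = 0.001
) -> list[ScoredPeak]:
    """Keep peaks whose FDR is strictly below ``fdr_threshold``.

    q-scores are on the -log10 scale, so FDR < t means qscore > -log10(t);
    a peak sitting exactly on the boundary (qscore == -log10 t) is removed.
    Input order is preserved.
    """
    if not (0.0 < fdr_threshold < 1.0):
        raise ValueError(f"fdr_threshold must be in (0, 1), got {fdr_threshold}")
    cutoff = -math.log10(fdr_threshold)
    return [p for p in peaks if p.qscore > cutoff]


def _merge_intervals(
    intervals: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge possibly-overlapping intervals into disjoint sorted ones.

    Abutting intervals ([a,b) and [b,c)) merge: coverage is per base and
    the union covers [a,c) without a gap.
    """
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_two(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two disjoint sorted interval lists (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _supporting_peak(peaks: list[ScoredPeak], start: int, end: int) -> ScoredPeak:
    """Overlapping peak with leftmost start; ties by lexicographic id."""
    best = None
    for p in peaks:
        if p.interval.start < end and start < p.interval.end:
            key = (p.interval.start, p.peak_id)
            if best is None or key < best[0]:
                best = (key, p)
    assert best is not None, "consensus region without covering peak"
    return best[1]


def intersect_replicates(
    replicate_peaks: Sequence[Sequence[ScoredPeak]],
    labels: Sequence[str] | None = None,
) -> list[ConsensusRegion]:
    """Maximal regions covered by >= 1 peak in every replicate.

    Computed per chromosome as the common per-base intersection of the
    replicates' covered sets.  Regions come back sorted by (chrom, start)
    and pairwise disjoint; region ids are ``cr1``, ``cr2``, ... in that
    order.
    """
    k = len(replicate_peaks)
    if k < 1:
        raise ValueError("need at least one replicate")
    if labels is None:
        labels = [f"rep{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per replicate required")

    # per chromosome, per replicate: peaks and merged coverage
    chroms: set[str] = set()
    by_chrom: list[dict[str, list[ScoredPeak]]] = []
    for peaks in replicate_peaks:
        d: dict[str, list[ScoredPeak]] = {}
        for p in peaks:
            d.setdefault(p.interval.chrom, []).append(p)
        by_chrom.append(d)
        chroms.update(d)

    regions: list[ConsensusRegion] = []
    counter = 0
    for chrom in sorted(chroms):
        covered = None
        for d in by_chrom:
            merged = _merge_intervals(
                [(p.interval.start, p.interval.end) for p in d.get(chrom, [])]
            )
            covered = merged if covered is None else _intersect_two(covered, merged)
            if not covered:
                break
        if not covered:
            continue
        for start, end in covered:
            counter += 1
            support = tuple(
                (
                    labels[r],
                    _supporting_peak(by_chrom[r].get(chrom, []), start, end).peak_id,
                )
                for r in range(k)
            )
            regions.append(
                ConsensusRegion(
                    interval=GenomicInterval(chrom, start, end),
                    region_id=f"cr{counter}",
                    support=support,
                )
            )
    return regions


def exclude_control(
    regions: Sequence[ConsensusRegion],
    control_peaks: Sequence[Sequence[ScoredPeak]],
    fdr_threshold: float = 0.001,
) -> list[ConsensusRegion]:
    """Drop regions overlapping (>= 1 bp) any qualifying control peak.

    Control peaks are held to the same FDR threshold as treatment peaks;
    surviving regions are returned unchanged, order preserved.
    """
    qualifying: dict[str, list[tuple[int, int]]] = {}
    for peaks in control_peaks:
        for p in filter_by_fdr(peaks, fdr_threshold):
            qualifying.setdefault(p.interval.chrom, []).append(
                (p.interval.start, p.interval.end)
            )
    merged = {c: _merge_intervals(v) for c, v in qualifying.items()}
    starts = {c: [s for s, _ in v] for c, v in merged.items()}

    kept = []
    for region in regions:
        iv = region.interval
        hits = merged.get(iv.chrom, [])
        # rightmost control interval starting before region end
        idx = bisect_right(starts.get(iv.chrom, []), iv.end - 1) - 1
        if idx >= 0 and hits[idx][1] > iv.start:
            continue
        kept.append(region)
    return kept


def consensus_regions(
    treatment_peaks: Sequence[Sequence[ScoredPeak]],
    control_peaks: Sequence[Sequence[ScoredPeak]],
    fdr_threshold: float = 0.001,
) -> list[ConsensusRegion]:
    """Full replicate-consistency filter.

    Peaks at FDR < threshold in all treatment replicates are intersected
    per base; regions touched by any control peak at the same threshold
    are removed.
    """
    filtered = [filter_by_fdr(peaks, fdr_threshold) for peaks in treatment_peaks]
    regions = intersect_replicates(filtered)
    return exclude_control(regions, control_peaks, fdr_threshold)
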