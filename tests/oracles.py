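"""Independent reference implementations used only to cross-check the
package.  These deliberately use the most literal (often slowest) approach:
per-base boolean arrays, all-pairs scans, exact integer hypergeometrics."""

from __future__ import annotations

import math

import numpy as np

from targetcall.annotation_io import GeneAnnotation, ScoredPeak


def per_base_consensus(
    replicate_peaks: list[list[ScoredPeak]],
    chrom_sizes: dict[str, int],
) -> list[tuple[str, int, int]]:
    """Maximal runs of bases covered by >= 1 peak in every replicate,
    computed with literal per-base boolean AND."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        covered_all = np.ones(n, dtype=bool)
        for peaks in replicate_peaks:
            covered = np.zeros(n, dtype=bool)
            for p in peaks:
                if p.interval.chrom == chrom:
                    covered[p.interval.start : p.interval.end] = True
            covered_all &= covered
        # maximal runs of True
        padded = np.concatenate(([False], covered_all, [False]))
        diffs = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(diffs[::2], diffs[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


def per_base_control_overlap(
    region: tuple[str, int, int],
    control_peaks: list[list[ScoredPeak]],
    qscore_cutoff: float,
) -> bool:
    """True when any base of the region is covered by a qualifying control
    peak (literal base scan)."""
    chrom, start, end = region
    for peaks in control_peaks:
        for p in peaks:
            if p.qscore <= qscore_cutoff or p.interval.chrom != chrom:
                continue
            for base in range(p.interval.start, p.interval.end):
                if start <= base < end:
                    return True
    return False


def brute_force_assignments(
    centers: list[tuple[str, int, str]],
    annotation: GeneAnnotation,
    upstream_bp: int = 3000,
    downstream_bp: int = 1500,
    anchor: str = "coding",
) -> set[tuple[str, str, str, int]]:
    """All-pairs application of the window and intervening-gene rules.

    ``centers`` holds (region_id, center, chrom).  Returns tuples of
    (region_id, gene_id, zone, offset).  The inner gene scan is vectorised
    but applies the literal per-pair conditions.
    """
    by_chrom: dict[str, list] = {}
    for g in annotation.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, genes in by_chrom.items():
        size = annotation.chrom_sizes[chrom]
        lo = np.empty(len(genes), dtype=np.int64)
        hi = np.empty(len(genes), dtype=np.int64)
        for i, g in enumerate(genes):
            span = g.cds_span if anchor == "coding" else g.tx_span
            if g.strand == "+":
                lo[i], hi[i] = span.start - upstream_bp, span.end + downstream_bp
            else:
                lo[i], hi[i] = span.start - downstream_bp, span.end + upstream_bp
        arrays[chrom] = (
            genes,
            np.array([g.tx_span.start for g in genes]),
            np.array([g.tx_span.end for g in genes]),
            np.maximum(lo, 0),
            np.minimum(hi, size),
        )

    out: set[tuple[str, str, str, int]] = set()
    for region_id, center, chrom in centers:
        if chrom not in arrays:
            continue
        genes, tx_s, tx_e, win_lo, win_hi = arrays[chrom]
        candidates = np.flatnonzero((win_lo <= center) & (center < win_hi))
        for i in candidates:
            g = genes[i]
            span = g.cds_span if anchor == "coding" else g.tx_span
            # intervening-gene veto on the open gap between center and span
            if center < span.start:
                gap_lo, gap_hi = center + 1, span.start
            elif center >= span.end:
                gap_lo, gap_hi = span.end, center
            else:
                gap_lo, gap_hi = 0, 0
            if gap_lo < gap_hi:
                mask = (tx_s < gap_hi) & (tx_e > gap_lo)
                mask[i] = False
                if mask.any():
                    continue
            # literal zone/offset arithmetic
            if g.strand == "+":
                if center < span.start:
                    zone, offset = "promoter", center - span.start
                elif center < span.end:
                    zone, offset = "transcribed", center - span.start
                else:
                    zone, offset = "downstream", center - span.end + 1
            else:
                if center >= span.end:
                    zone, offset = "promoter", -(center - span.end + 1)
                elif center >= span.start:
                    zone, offset = "transcribed", span.end - 1 - center
                else:
                    zone, offset = "downstream", span.start - center
            out.add((region_id, g.gene_id, zone, offset))
    return out


def fisher_two_tailed_exact(
    n_both: int, n_a_only: int, n_b_only: int, n_neither: int
) -> float:
    """Two-tailed Fisher p by exhaustive enumeration with exact integer
    binomials (probability-mass rule, relative slack 1e-7 on ties)."""
    n_a = n_both + n_a_only
    n_b = n_both + n_b_only
    N = n_both + n_a_only + n_b_only + n_neither
    k_min = max(0, n_a + n_b - N)
    k_max = min(n_a, n_b)
    denom = math.comb(N, n_b)
    num_obs = math.comb(n_a, n_both) * math.comb(N - n_a, n_b - n_both)
    total = 0
    for k in range(k_min, k_max + 1):
        num_k = math.comb(n_a, k) * math.comb(N - n_a, n_b - k)
        if num_k <= num_obs * (1 + 1e-7):
            total += num_k
    return total / denom


def empirical_p_counts(obs_frac: float, null_fracs: list[float]) -> tuple[float, float]:
    """Add-one empirical p-values by direct counting (enrichment, depletion)."""
    B = len(null_fracs)
    ge = sum(1 for f in null_fracs if f >= obs_frac)
    le = sum(1 for f in null_fracs if f <= obs_frac)
    return (ge + 1) / (B + 1), (le + 1) / (B + 1)
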