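"""Seeded synthetic genomes and replicate peak calls.

The generator emulates the input the pipeline is built for: MACS2-style
scored peak calls over an annotated genome, with latent binding sites
planted in the windows of a designated true-target gene set, per-replicate
edge jitter and score noise, genome-wide background peaks, and artifact
sites that show up in treatment *and* control replicates.  Everything is a
pure function of :class:`SimulationParams` (including its seed), so every
downstream stage is testable without any external data.

q-scores are on the -log10 FDR scale of narrowPeak column 9, so the
default true-site mean of 6 sails through an "FDR < 0.001" filter
(qscore > 3) while the background mean of 1.5 almost never does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    ScoredPeak,
)

__all__ = [
    "SimulationParams",
    "SimulatedTruth",
    "simulate_genome",
    "simulate_peaksets",
    "simulate_reference_set",
]

#: margin kept free at each chromosome end so no gene window is clipped
_EDGE_MARGIN = 3500
#: minimum intergenic gap; the worst adjacent-window case is a divergent
#: pair (two 3 kb upstream extensions face each other), so 6 kb guarantees
#: that gene windows are pairwise disjoint and every consensus region can
#: fall in at most one window
_MIN_GAP = 6000


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults are the package's reference
    conditions (3 x 2 Mb genome, 300 genes, 60 true targets, 3 + 3
    replicates)."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length_mean: float = 2000.0
    gene_length_sd: float = 500.0
    n_true_targets: int = 60
    n_treatment_reps: int = 3
    n_control_reps: int = 3
    promoter_weight: float = 0.6
    body_weight: float = 0.1
    downstream_weight: float = 0.3
    peak_width_mean: float = 300.0
    peak_width_sd: float = 80.0
    jitter_sd: float = 20.0
    true_qscore_mean: float = 6.0
    background_qscore_mean: float = 1.5
    n_background_peaks_per_rep: int = 300
    n_artifact_sites: int = 10
    ref_set_size: int = 100
    ref_overlap: int = 40
    upstream_bp: int = 3000
    downstream_bp: int = 1500

    def __post_init__(self) -> None:
        w = self.promoter_weight + self.body_weight + self.downstream_weight
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"zone weights must sum to 1, got {w}")
        if min(self.promoter_weight, self.body_weight, self.downstream_weight) < 0:
            raise ValueError("zone weights must be non-negative")
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets cannot exceed n_genes")
        if self.ref_overlap > min(self.ref_set_size, self.n_true_targets):
            raise ValueError(
                "ref_overlap cannot exceed min(ref_set_size, n_true_targets)"
            )
        for name in ("n_chroms", "chrom_length", "n_treatment_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated experiment."""

    true_target_ids: set[str]
    latent_sites: dict[str, tuple[str, int]] = field(default_factory=dict)
    latent_zones: dict[str, str] = field(default_factory=dict)
    artifact_positions: list[tuple[str, int]] = field(default_factory=list)


def _stage_rng(params: SimulationParams, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    return np.random.default_rng([params.seed, stage])


def simulate_genome(params: SimulationParams) -> GeneAnnotation:
    """Lay out non-overlapping genes with >= 6 kb intergenic gaps.

    Genes are split as evenly as possible across chromosomes, lengths drawn
    from a truncated normal, strands random; the coding span equals the
    transcribed span.  Raises if the requested genes cannot be packed.
    """
    rng = _stage_rng(params, 0)
    chrom_sizes = {
        f"chr{i + 1}": params.chrom_length for i in range(params.n_chroms)
    }
    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        cursor = _EDGE_MARGIN
        for _ in range(per_chrom[ci]):
            gid += 1
            length = max(
                200,
                int(round(rng.normal(params.gene_length_mean, params.gene_length_sd))),
            )
            gap = int(rng.integers(_MIN_GAP, _MIN_GAP + 3000))
            if genes and genes[-1].chrom == chrom:
                cursor = genes[-1].tx_span.end + gap
            if cursor + length > params.chrom_length - _EDGE_MARGIN:
                raise ValueError(
                    f"cannot place {params.n_genes} genes of mean length "
                    f"{params.gene_length_mean} on {params.n_chroms} x "
                    f"{params.chrom_length} bp chromosomes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, cursor, cursor + length)
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_span=span,
                    cds_span=span,
                )
            )
    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def _draw_site_in_zone(
    rng: np.random.Generator, gene: GeneModel, zone: str, up: int, down: int
) -> int:
    """Uniform position inside one strand-aware zone of a gene."""
    s = gene.cds_span
    if gene.strand == "+":
        if zone == "promoter":
            return int(rng.integers(s.start - up, s.start))
        if zone == "transcribed":
            return int(rng.integers(s.start, s.end))
        return int(rng.integers(s.end, s.end + down))
    if zone == "promoter":
        return int(rng.integers(s.end, s.end + up))
    if zone == "transcribed":
        return int(rng.integers(s.start, s.end))
    return int(rng.integers(s.start - down, s.start))


def _site_peak(
    rng: np.random.Generator,
    chrom: str,
    site: int,
    width: int,
    chrom_len: int,
    jitter_sd: float,
    qscore_mean: float,
    peak_id: str,
) -> ScoredPeak:
    """Peak centered on a latent site, with independent edge jitter."""
    start = site - width // 2
    end = start + width
    if jitter_sd > 0:
        start += int(round(rng.normal(0.0, jitter_sd)))
        end += int(round(rng.normal(0.0, jitter_sd)))
    start = max(0, start)
    end = min(chrom_len, max(end, start + 1))
    qscore = max(0.0, float(rng.normal(qscore_mean, 0.5)))
    summit = min(max(site - start, 0), end - start - 1)
    return ScoredPeak(
        interval=GenomicInterval(chrom, start, end),
        peak_id=peak_id,
        qscore=qscore,
        summit_offset=summit,
    )


def _background_peak(
    rng: np.random.Generator,
    annotation: GeneAnnotation,
    params: SimulationParams,
    peak_id: str,
) -> ScoredPeak:
    chroms = sorted(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
    chrom_len = annotation.chrom_sizes[chrom]
    width = max(50, int(round(rng.normal(params.peak_width_mean, params.peak_width_sd))))
    site = int(rng.integers(0, chrom_len))
    start = max(0, site - width // 2)
    end = min(chrom_len, max(start + 1, start + width))
    qscore = max(0.0, float(rng.normal(params.background_qscore_mean, 0.5)))
    return ScoredPeak(
        interval=GenomicInterval(chrom, start, end),
        peak_id=peak_id,
        qscore=qscore,
        summit_offset=min(site - start, end - start - 1) if site >= start else 0,
    )


def simulate_peaksets(
    annotation: GeneAnnotation, params: SimulationParams
) -> tuple[list[list[ScoredPeak]], list[list[ScoredPeak]], SimulatedTruth]:
    """Per-replicate peak calls plus the ground truth behind them.

    Each true target gets one latent site drawn from the configured zone
    mixture; every treatment replicate sees a peak on it (shared width,
    per-replicate edge jitter and q-score noise).  Background peaks land
    uniformly in every replicate; artifact sites produce peaks in all
    treatment *and* control replicates.
    """
    rng = _stage_rng(params, 1)
    genes = annotation.by_id()
    gene_ids = sorted(genes)

    if params.n_true_targets:
        targets = [
            gene_ids[i]
            for i in sorted(
                rng.choice(len(gene_ids), size=params.n_true_targets, replace=False)
            )
        ]
    else:
        targets = []

    truth = SimulatedTruth(true_target_ids=set(targets))
    weights = [params.promoter_weight, params.body_weight, params.downstream_weight]
    site_widths: dict[str, int] = {}
    for gid in targets:
        zone = ("promoter", "transcribed", "downstream")[
            int(rng.choice(3, p=weights))
        ]
        site = _draw_site_in_zone(
            rng, genes[gid], zone, params.upstream_bp, params.downstream_bp
        )
        truth.latent_sites[gid] = (genes[gid].chrom, site)
        truth.latent_zones[gid] = zone
        site_widths[gid] = max(
            50, int(round(rng.normal(params.peak_width_mean, params.peak_width_sd)))
        )

    chroms = sorted(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    artifact_widths: list[int] = []
    for _ in range(params.n_artifact_sites):
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        pos = int(rng.integers(0, annotation.chrom_sizes[chrom]))
        truth.artifact_positions.append((chrom, pos))
        artifact_widths.append(
            max(50, int(round(rng.normal(params.peak_width_mean, params.peak_width_sd))))
        )

    def replicate(label: str, with_true_sites: bool) -> list[ScoredPeak]:
        peaks: list[ScoredPeak] = []
        n = 0
        if with_true_sites:
            for gid in targets:
                chrom, site = truth.latent_sites[gid]
                n += 1
                peaks.append(
                    _site_peak(
                        rng,
                        chrom,
                        site,
                        site_widths[gid],
                        annotation.chrom_sizes[chrom],
                        params.jitter_sd,
                        params.true_qscore_mean,
                        f"{label}_p{n}",
                    )
                )
        for (chrom, pos), width in zip(truth.artifact_positions, artifact_widths):
            n += 1
            peaks.append(
                _site_peak(
                    rng,
                    chrom,
                    pos,
                    width,
                    annotation.chrom_sizes[chrom],
                    params.jitter_sd,
                    params.true_qscore_mean,
                    f"{label}_p{n}",
                )
            )
        for _ in range(params.n_background_peaks_per_rep):
            n += 1
            peaks.append(_background_peak(rng, annotation, params, f"{label}_p{n}"))
        return peaks

    treatment = [
        replicate(f"t{r + 1}", with_true_sites=True)
        for r in range(params.n_treatment_reps)
    ]
    control = [
        replicate(f"c{r + 1}", with_true_sites=False)
        for r in range(params.n_control_reps)
    ]
    return treatment, control, truth


def simulate_reference_set(
    truth: SimulatedTruth,
    annotation: GeneAnnotation,
    params: SimulationParams,
) -> set[str]:
    """Reference gene set with a controlled overlap with the true targets.

    ``ref_overlap`` members are sampled from the true targets and the rest
    from non-targets, both without replacement; stands in for an
    independently published target list.
    """
    rng = _stage_rng(params, 2)
    targets = sorted(truth.true_target_ids)
    non_targets = sorted(annotation.gene_ids - truth.true_target_ids)
    n_rest = params.ref_set_size - params.ref_overlap
    if n_rest > len(non_targets):
        raise ValueError(
            f"reference set needs {n_rest} non-targets but only "
            f"{len(non_targets)} exist"
        )
    chosen: set[str] = set()
    if params.ref_overlap:
        chosen.update(
            targets[i]
            for i in rng.choice(len(targets), size=params.ref_overlap, replace=False)
        )
    if n_rest:
        chosen.update(
            non_targets[i]
            for i in rng.choice(len(non_targets), size=n_rest, replace=False)
        )
    return chosen


def write_truth_table(truth: SimulatedTruth, sink) -> None:
    """TSV of the planted sites: gene_id, chrom, site_position, zone."""
    sink.write("gene_id\tchrom\tsite_position\tzone\n")
    for gid in sorted(truth.latent_sites):
        chrom, pos = truth.latent_sites[gid]
        sink.write(f"{gid}\t{chrom}\t{pos}\t{truth.latent_zones[gid]}\n")
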