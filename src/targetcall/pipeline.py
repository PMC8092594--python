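"""End-to-end orchestration: simulate/load -> consensus -> assign -> enrich -> overlap.

One flat config document (YAML) drives the run; a single seed controls every
stochastic stage (per-stage streams are derived from it), so a run is fully
reproducible.  Each stage writes its output to ``output_dir`` and the run
ends with a machine-readable JSON report of record counts and test results.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Sequence

from . import __version__
from .annotation_io import (
    GeneAnnotation,
    ScoredPeak,
    read_gene_list,
    read_gff3,
    read_narrowpeak,
    write_gene_list,
    write_gff3,
    write_narrowpeak,
)
from .assign import TargetAssignment, assign_regions, target_gene_set
from .consensus import (
    ConsensusRegion,
    exclude_control,
    filter_by_fdr,
    intersect_replicates,
)
from .enrichment import (
    bootstrap_null,
    enrichment_test,
    metagene_histogram,
    observed_zone_counts,
)
from .overlap import contingency, fisher_exact_two_tailed
from .simulate import (
    SimulationParams,
    simulate_genome,
    simulate_peaksets,
    simulate_reference_set,
    write_truth_table,
)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

log = logging.getLogger("targetcall")

_TOP_DEFAULTS: dict[str, Any] = {
    "fdr_threshold": 0.001,
    "upstream_bp": 3000,
    "downstream_bp": 1500,
    "assignment_anchor": "coding",
    "enrichment_anchor": "transcript",
    "B": 10000,
    "alpha": 0.05,
    "bin_width": 100,
    "seed": 0,
    "output_dir": "targetcall_out",
}

_INPUT_KEYS = {"annotation", "treatment", "control", "reference_set", "universe"}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted run configuration."""

    seed: int
    output_dir: Path
    fdr_threshold: float = 0.001
    upstream_bp: int = 3000
    downstream_bp: int = 1500
    assignment_anchor: str = "coding"
    enrichment_anchor: str = "transcript"
    B: int = 10000
    alpha: float = 0.05
    bin_width: int = 100
    simulation: SimulationParams | None = None
    inputs: dict[str, Any] | None = None


@dataclass
class RunReport:
    """Per-stage record counts plus the two statistical results."""

    config: dict[str, Any]
    counts: dict[str, int]
    enrichment: list[dict[str, Any]] | None
    overlap: dict[str, Any] | None
    target_genes: list[str]
    version: str = __version__
    seed: int = 0
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "counts": self.counts,
            "target_genes": self.target_genes,
            "enrichment": self.enrichment,
            "overlap": self.overlap,
        }


def validate_config(raw: dict[str, Any]) -> PipelineConfig:
    """Type- and range-check a raw config document; fill defaults.

    Unknown keys are rejected rather than ignored, and every defaulted
    field is logged, so a typo cannot silently change an analysis.
    """
    if not isinstance(raw, dict):
        raise ValueError("config document must be a mapping")
    raw = dict(raw)
    sim_block = raw.pop("simulation", None)
    input_block = raw.pop("inputs", None)
    if (sim_block is None) == (input_block is None):
        raise ValueError("exactly one of 'simulation' or 'inputs' must be given")

    unknown = set(raw) - set(_TOP_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    values = dict(_TOP_DEFAULTS)
    for key, default in _TOP_DEFAULTS.items():
        if key in raw:
            values[key] = raw[key]
        else:
            log.info("config: %s defaulted to %r", key, default)

    if not (0.0 < float(values["fdr_threshold"]) < 1.0):
        raise ValueError("fdr_threshold must lie in (0, 1)")
    if not (0.0 < float(values["alpha"]) < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    for key in ("upstream_bp", "downstream_bp"):
        if int(values[key]) < 0:
            raise ValueError(f"{key} must be >= 0")
    for key in ("B", "bin_width"):
        if int(values[key]) < 1:
            raise ValueError(f"{key} must be >= 1")
    for key, allowed in (
        ("assignment_anchor", ("coding", "transcript")),
        ("enrichment_anchor", ("coding", "transcript")),
    ):
        if values[key] not in allowed:
            raise ValueError(f"{key} must be one of {allowed}")

    simulation = None
    inputs = None
    if sim_block is not None:
        if not isinstance(sim_block, dict):
            raise ValueError("'simulation' must be a mapping")
        sim_fields = {f.name for f in dc_fields(SimulationParams)} - {"seed"}
        unknown = set(sim_block) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(unknown)}")
        simulation = SimulationParams(seed=int(values["seed"]), **sim_block)
    else:
        if not isinstance(input_block, dict):
            raise ValueError("'inputs' must be a mapping")
        unknown = set(input_block) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input key(s): {sorted(unknown)}")
        for key in ("annotation", "treatment", "control"):
            if key not in input_block:
                raise ValueError(f"inputs block requires {key!r}")
        inputs = input_block

    return PipelineConfig(
        seed=int(values["seed"]),
        output_dir=Path(values["output_dir"]),
        fdr_threshold=float(values["fdr_threshold"]),
        upstream_bp=int(values["upstream_bp"]),
        downstream_bp=int(values["downstream_bp"]),
        assignment_anchor=str(values["assignment_anchor"]),
        enrichment_anchor=str(values["enrichment_anchor"]),
        B=int(values["B"]),
        alpha=float(values["alpha"]),
        bin_width=int(values["bin_width"]),
        simulation=simulation,
        inputs=inputs,
    )


def _write_consensus_bed(regions: Sequence[ConsensusRegion], path: Path) -> None:
    with path.open("w") as fh:
        for r in regions:
            prov = ",".join(f"{rep}:{pid}" for rep, pid in r.support)
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.region_id}|{prov}\n"
            )


def _write_assignments(assignments: Sequence[TargetAssignment], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("region_id\tgene_id\tzone\toffset\n")
        for a in assignments:
            fh.write(f"{a.region_id}\t{a.gene_id}\t{a.zone}\t{a.offset}\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; write intermediates and a JSON report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    # --- stage 0: obtain inputs -------------------------------------------
    reference_set: set[str] | None = None
    universe: set[str] | None = None
    if config.simulation is not None:
        params = config.simulation
        annotation = simulate_genome(params)
        treatment, control, truth = simulate_peaksets(annotation, params)
        reference_set = simulate_reference_set(truth, annotation, params)
        with (out / "genes.gff3").open("w") as fh:
            write_gff3(annotation, fh)
        for label, reps in (("treatment", treatment), ("control", control)):
            for i, peaks in enumerate(reps, start=1):
                with (out / f"{label}_rep{i}.narrowPeak").open("w") as fh:
                    write_narrowpeak(peaks, fh)
        with (out / "truth_sites.tsv").open("w") as fh:
            write_truth_table(truth, fh)
        with (out / "reference_set.txt").open("w") as fh:
            write_gene_list(reference_set, fh)
    else:
        assert config.inputs is not None
        with open(config.inputs["annotation"]) as fh:
            annotation = read_gff3(fh)
        treatment = []
        for p in config.inputs["treatment"]:
            with open(p) as fh:
                treatment.append(read_narrowpeak(fh))
        control = []
        for p in config.inputs.get("control", []):
            with open(p) as fh:
                control.append(read_narrowpeak(fh))
        if "reference_set" in config.inputs:
            with open(config.inputs["reference_set"]) as fh:
                reference_set = read_gene_list(fh)
        if "universe" in config.inputs:
            with open(config.inputs["universe"]) as fh:
                universe = read_gene_list(fh)

    n_peaks_in = sum(len(r) for r in treatment)
    filtered = [filter_by_fdr(r, config.fdr_threshold) for r in treatment]
    n_passing = sum(len(r) for r in filtered)
    log.info("peaks in: %d; passing FDR < %g: %d", n_peaks_in, config.fdr_threshold, n_passing)

    # --- consensus --------------------------------------------------------
    regions = intersect_replicates(filtered)
    regions = exclude_control(regions, control, config.fdr_threshold)
    _write_consensus_bed(regions, out / "consensus.bed")
    log.info("consensus regions after control exclusion: %d", len(regions))

    # --- assignment -------------------------------------------------------
    assignments = assign_regions(
        regions,
        annotation,
        upstream_bp=config.upstream_bp,
        downstream_bp=config.downstream_bp,
        anchor=config.assignment_anchor,  # type: ignore[arg-type]
    )
    _write_assignments(assignments, out / "assignments.tsv")
    targets = target_gene_set(assignments)
    with (out / "targets.txt").open("w") as fh:
        write_gene_list(targets, fh)
    log.info("assignments: %d; target genes: %d", len(assignments), len(targets))

    # --- enrichment -------------------------------------------------------
    enrichment_report = None
    if assignments:
        hist = metagene_histogram(
            assignments,
            annotation,
            bin_width=config.bin_width,
            assignment_anchor=config.assignment_anchor,  # type: ignore[arg-type]
        )
        with (out / "metagene_histogram.tsv").open("w") as fh:
            fh.write("bin_start\tbin_end\tanchor\tcount\n")
            for lo, hi, anchor, count in hist.rows():
                fh.write(f"{lo}\t{hi}\t{anchor}\t{count}\n")
        observed = observed_zone_counts(assignments)
        null = bootstrap_null(
            annotation,
            set(targets),
            n_observed=observed.total,
            B=config.B,
            seed=config.seed + 3,
            upstream_bp=config.upstream_bp,
            downstream_bp=config.downstream_bp,
            anchor=config.enrichment_anchor,  # type: ignore[arg-type]
        )
        results = enrichment_test(observed, null, alpha=config.alpha)
        enrichment_report = [
            {
                "zone": r.zone,
                "observed_fraction": r.observed_fraction,
                "null_mean_fraction": float(r.null_fractions.mean()),
                "p_enriched": r.p_enriched,
                "p_depleted": r.p_depleted,
                "direction": r.direction,
            }
            for r in results
        ]

    # --- overlap ----------------------------------------------------------
    overlap_report = None
    if reference_set is not None:
        if universe is None:
            universe = annotation.gene_ids
        table = contingency(set(targets), reference_set, universe, strict=False)
        res = fisher_exact_two_tailed(table)
        overlap_report = {
            "n_both": table.n_both,
            "n_a_only": table.n_a_only,
            "n_b_only": table.n_b_only,
            "n_neither": table.n_neither,
            "universe_size": table.universe_size,
            "odds_ratio": res.odds_ratio,
            "fold_enrichment": res.fold_enrichment,
            "p_two_tailed": res.p_two_tailed,
        }

    finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    config_echo = {
        "seed": config.seed,
        "output_dir": str(config.output_dir),
        "fdr_threshold": config.fdr_threshold,
        "upstream_bp": config.upstream_bp,
        "downstream_bp": config.downstream_bp,
        "assignment_anchor": config.assignment_anchor,
        "enrichment_anchor": config.enrichment_anchor,
        "B": config.B,
        "alpha": config.alpha,
        "bin_width": config.bin_width,
        "mode": "simulation" if config.simulation is not None else "inputs",
    }
    report = RunReport(
        config=config_echo,
        counts={
            "peaks_in": n_peaks_in,
            "peaks_passing_fdr": n_passing,
            "consensus_regions": len(regions),
            "assignments": len(assignments),
            "target_genes": len(targets),
        },
        enrichment=enrichment_report,
        overlap=overlap_report,
        target_genes=targets,
        seed=config.seed,
        started=started,
        finished=finished,
    )
    with (out / "report.json").open("w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
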