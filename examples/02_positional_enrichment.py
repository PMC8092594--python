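"""Where do binding sites sit relative to their target genes?

Takes the assignments from a simulated run and asks whether the observed
promoter / transcribed / downstream split differs from uniformly placed
positions inside the same gene windows (the bootstrap null, B = 10,000
simulations; empirical p-values use the add-one rule and are never zero).
"""

from targetcall import (
    SimulationParams,
    assign_regions,
    bootstrap_null,
    consensus_regions,
    enrichment_test,
    metagene_histogram,
    observed_zone_counts,
    simulate_genome,
    simulate_peaksets,
    target_gene_set,
)

params = SimulationParams(seed=17)
annotation = simulate_genome(params)
treatment, control, _ = simulate_peaksets(annotation, params)
regions = consensus_regions(treatment, control)
assignments = assign_regions(regions, annotation)
targets = set(target_gene_set(assignments))

observed = observed_zone_counts(assignments)
null = bootstrap_null(annotation, targets, observed.total, B=10_000, seed=20)
for r in enrichment_test(observed, null):
    print(
        f"{r.zone:11s} observed {r.observed_fraction:.3f}  "
        f"null mean {float(r.null_fractions.mean()):.3f}  "
        f"p_enriched {r.p_enriched:.2g}  p_depleted {r.p_depleted:.2g}  "
        f"-> {r.direction}"
    )
# the observed fraction is the share of consensus-region centers in each
# zone; the null mean is what uniform placement inside the same windows
# would give (the windows' base composition).

hist = metagene_histogram(assignments, annotation, bin_width=100)
upstream = sum(hist.upstream_bins.values())
print(f"\nmetagene histogram: {hist.total} centers "
      f"({upstream} upstream of the transcript start)")
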