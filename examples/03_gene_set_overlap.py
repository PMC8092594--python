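"""Do two target-gene sets share more genes than chance predicts?

Compares the recovered ChIP target set with a simulated reference list
(100 genes, 40 of them true targets) over the full gene universe, using
the two-tailed Fisher's exact test on the 2x2 membership table.
"""

from targetcall import (
    SimulationParams,
    assign_regions,
    consensus_regions,
    contingency,
    fisher_exact_two_tailed,
    simulate_genome,
    simulate_peaksets,
    simulate_reference_set,
    target_gene_set,
)

params = SimulationParams(seed=17)
annotation = simulate_genome(params)
treatment, control, truth = simulate_peaksets(annotation, params)
reference = simulate_reference_set(truth, annotation, params)

regions = consensus_regions(treatment, control)
targets = set(target_gene_set(assign_regions(regions, annotation)))

table = contingency(targets, reference, annotation.gene_ids)
result = fisher_exact_two_tailed(table)
expected = table.n_a * table.n_b / table.universe_size
print(f"targets: {table.n_a}   reference: {table.n_b}   "
      f"universe: {table.universe_size}")
print(f"shared genes: {table.n_both}  (chance expectation: {expected:.1f})")
print(f"fold enrichment: {result.fold_enrichment:.2f}")
print(f"odds ratio: {result.odds_ratio:.1f}")
print(f"two-tailed Fisher p: {result.p_two_tailed:.3g}")
# a small p with fold enrichment > 1 says the two regulators bind an
# overlapping set of genes far more often than random sets of these
# sizes would.
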