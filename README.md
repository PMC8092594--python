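# targetcall

Identify the direct target genes of a DNA-binding protein from replicated
ChIP-seq peak calls.

ChIP-seq for a tagged transcription factor yields, per biological
replicate, a set of scored peaks (MACS2-style narrowPeak, with a −log₁₀
q-value per peak).  Turning those peaks into a defensible target-gene list
requires four decisions that `targetcall` implements as one tested
pipeline:

1. **Replicate-consensus filtering.**  Keep only genomic regions supported
   at FDR < 0.001 (q-score > 3) in *every* treatment replicate and
   overlapped by no qualifying control (untagged wild-type) peak.  Support
   is evaluated per base — a consensus region is a maximal interval covered
   by all replicates' peaks simultaneously.
2. **Window-based target assignment.**  A consensus region (located at its
   center) is associated with a gene when it falls within 3 kb upstream to
   1.5 kb downstream of the gene's coding sequence (strand-aware, boundary
   inclusive) and no other gene's transcribed span lies between the region
   and that coding sequence.  Divergent promoters may legitimately yield
   two target genes for one region.
3. **Positional-enrichment testing.**  The promoter / transcribed /
   downstream split of the observed region centers is compared against a
   bootstrap null of positions placed uniformly inside the same target-gene
   windows (default B = 10,000 simulations).  Empirical p-values use the
   add-one estimator p = (r + 1)/(B + 1), separately for enrichment and
   depletion in each zone.
4. **Target-set overlap.**  Agreement with an independent gene list (e.g.
   the published targets of another regulator) is scored with a two-tailed
   Fisher's exact test on the 2×2 membership table over an explicit gene
   universe, with fold enrichment n_both·N / (n_A·n_B).

A seeded synthetic-data generator (`targetcall.simulate`) produces genomes,
replicate peak calls with positional jitter, score noise, background and
control-artifact peaks, plus the ground truth behind them — so the whole
chain is testable end to end without any external data.

## Worked example

```python
from targetcall import (SimulationParams, simulate_genome, simulate_peaksets,
                        consensus_regions, assign_regions, target_gene_set)

params = SimulationParams(seed=17)            # 300 genes, 60 true targets, 3+3 reps
annotation = simulate_genome(params)
treatment, control, truth = simulate_peaksets(annotation, params)

regions = consensus_regions(treatment, control, fdr_threshold=0.001)
targets = set(target_gene_set(assign_regions(regions, annotation)))
```

Running `python examples/01_simulate_and_call_targets.py` prints:

```
treatment peaks per replicate: [370, 370, 370]
consensus regions (all treatment, no control): 60
recovered target genes: 60  (planted: 60)
precision: 1.000   recall: 1.000
```

Each replicate carries 370 peaks (60 true sites + 10 control-shared
artifacts + 300 background); the consensus filter strips everything that is
not reproducibly treatment-specific, and the window rule maps the 60
surviving regions back onto exactly the 60 genes whose windows received a
planted site.  `examples/02_positional_enrichment.py` continues with the
zone test:

```
promoter    observed 0.617  null mean 0.465  p_enriched 0.013  p_depleted 0.99  -> enriched
transcribed observed 0.133  null mean 0.303  p_enriched 1  p_depleted 0.0023  -> depleted
downstream  observed 0.250  null mean 0.233  p_enriched 0.42  p_depleted 0.69  -> neither
```

— binding is concentrated in promoters and depleted in gene bodies
relative to the windows' base composition, as expected for a transcription
factor.  `examples/03_gene_set_overlap.py` finds 40 shared genes between
the 60 recovered targets and a 100-gene reference list over a 300-gene
universe (chance expectation 20, fold enrichment 2.0, two-tailed Fisher
p ≈ 3.6 × 10⁻⁹).

The same analysis runs from the shell:

```bash
targetcall run --config run.yaml        # full pipeline
targetcall simulate / consensus / assign / enrich / overlap   # single stages
```

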