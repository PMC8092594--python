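# Methods

## Problem setting

A transcription factor is ChIP-sequenced in k treatment replicates (tagged
line) and m control replicates (untagged wild type).  An external peak
caller has already reduced the reads to scored peaks; `targetcall` consumes
those peaks (narrowPeak, q-value = −log₁₀ FDR in column 9) plus a gene
annotation (GFF3) and produces a target-gene list with positional and
overlap statistics.  All internal coordinates are 0-based half-open;
GFF3's 1-based inclusive coordinates are converted exactly once, at the
I/O boundary.

## Consensus filter

A peak *qualifies* at threshold t when its FDR is strictly below t, i.e.
qscore > −log₁₀ t; the default t = 0.001 means qscore > 3, and a peak
sitting exactly on the boundary is excluded.  A **consensus region** is a
maximal interval in which every treatment replicate has at least one
qualifying peak covering every base (a per-base AND across replicates, not
pairwise chaining), from which any region overlapping — by one base or
more — a control peak qualifying at the same threshold is removed.
Consequences of these choices:

* intersection is symmetric in the replicates, and adding a replicate can
  only shrink or delete regions;
* with a single replicate the regions are simply that replicate's merged
  peaks;
* abutting peaks within one replicate merge (coverage has no gap), so a
  region can, in principle, be chained across two overlapping same-replicate
  peaks; the recorded supporting peak per replicate is then the overlapping
  peak with the leftmost start (ties: lexicographic id).  With
  non-overlapping peak calls per replicate — the normal situation for a
  punctate-mark peak caller — every region lies inside each supporting peak.

Whether the original control exclusion used the same threshold on control
peaks is not documented anywhere we could rely on; applying the identical
cutoff to both arms is the symmetric choice and is exposed as a parameter.

## Target assignment

Each gene contributes a strand-aware window: coding span extended 3,000 bp
on the 5′ side and 1,500 bp on the 3′ side, clipped to the chromosome.
A consensus region is located at its center (midpoint, floor).  The region
is assigned to a gene when

(a) the center lies in the gene's window — boundaries inclusive, so a
    center exactly 3,000 bp upstream still qualifies; and
(b) no *other* gene's transcribed span overlaps the open interval between
    the center and the nearest edge of the candidate's coding span (no
    check when the center is inside the coding span).

The veto is evaluated per candidate, so one region may be assigned to two
genes facing each other across a shared intergenic stretch (divergent
promoters).  Offsets are signed: negative upstream of the anchor's 5′
edge, 0-based inside the span, +1 for the first base past the 3′ edge.
Genes without annotated CDS inherit their transcribed span as coding span,
which keeps the rule total for non-coding genes.

Alternatives we considered and rejected as defaults: any-overlap membership
instead of the center (couples results to peak widths), and requiring the
intervening gene to be *contained* in the gap rather than overlap it
(weaker reading of "intervening"); both remain easy to add as options, but
the defaults are the strictest literal reading and are what the tests pin
down.

## Positional enrichment

Observed statistic: the fraction of assigned region centers per zone
(promoter / transcribed / downstream, classified against the transcript
span by default — assignment anchors on the coding span, the positional
view on the transcript span; both anchors are parameters).

Null model: positions drawn uniformly over the genome and retained only
when they land inside a target gene's window, until the observed count n is
matched; each simulation classifies its n positions into zones.  Because
uniform draws conditioned on landing in the window union are exactly
uniform *on* that union, the per-simulation zone counts follow a
multinomial over the zones' base-pair composition; the implementation
samples those counts directly (after resolving window overlaps per base
with priority transcribed > promoter > downstream and the reference
generator guarantees disjoint windows anyway).  This is the identical null
distribution, computed without rejection loops, and is deterministic given
the seed.

Empirical p-values use the add-one estimator p = (r + 1)/(B + 1) per side
(enrichment: null fraction ≥ observed; depletion: ≤), so p ∈ [1/(B+1), 1]
and a zone can never be reported at p = 0.  Fraction comparisons are done
on integer cross-products, so ties are exact rather than float-dependent.
B defaults to 10,000.

The metagene histogram bins center offsets at 100 bp (a display default;
bin width is a parameter): promoter and the 5′ half of the transcribed
span relative to the transcript start, the 3′ half and downstream relative
to the transcript end, with the span split at its midpoint.

## Set overlap

Membership of the target set and a reference set over an explicit universe
(default: all genes in the annotation — the universe is always reported,
never implicit) gives a 2×2 table; significance is the two-tailed Fisher's
exact test under the probability-mass rule (sum of hypergeometric
probabilities of all tables with the observed margins that are at most as
probable as the observed table, with 1e-7 relative slack on ties —
`scipy.stats.fisher_exact` semantics, which the test suite verifies against
exhaustive integer enumeration for every table with N ≤ 30).  Reported
alongside: sample odds ratio (∞ when the denominator cell is empty) and
fold enrichment n_both·N/(n_A·n_B).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not read-level signal:

| parameter | default | why |
|---|---|---|
| genome | 3 chromosomes × 2 Mb | large enough that background rarely collides with windows |
| genes | 300, length ~N(2000, 500²) bp, min 200 | compact plant-like gene size |
| intergenic gap | uniform 6–9 kb | ≥ 6 kb makes adjacent windows disjoint even for divergent pairs (two facing 3 kb upstream extensions), so every region has at most one candidate window by construction |
| true targets | 60 | enough for stable precision/recall at desk scale |
| zone mixture | 0.6 / 0.1 / 0.3 (promoter/body/downstream) | promoter- and downstream-shifted relative to the windows' ≈0.46/0.31/0.23 base composition, body-depleted — the canonical transcription-factor profile |
| replicates | 3 treatment + 3 control | standard design |
| peak width | ~N(300, 80²) bp, min 50, shared per site | punctate-mark scale |
| edge jitter | N(0, 20²) bp per replicate, both edges independent | exercises the per-base intersection nontrivially |
| q-scores | true sites ~N(6, 0.5²), background ~N(1.5, 0.5²), truncated at 0 | true sites essentially always pass qscore > 3; background passes with ≈2·10⁻³ probability per peak, and never in all three replicates at the same spot |
| background | 300 peaks/replicate, uniform | realistic noise floor |
| artifacts | 10 sites in *all* replicates including controls | the class of peak the control exclusion exists to remove |
| reference set | 100 genes, 40 overlapping true targets | hypergeometric expectation is 20, so the overlap test has signal |

Peak-width and score distributions are calibration choices of this
package, not measured values.  Each stage draws from an independent
seeded stream (`default_rng([seed, stage])`), so genomes, peak sets and
reference sets are individually reproducible and the whole simulation is a
pure function of the parameter record.

What passing tests on this generator shows — and does not.  The generator
produces one latent site per target, symmetric jitter, and no
replicate-efficiency differences, coverage profiles or mappability
structure.  Recovery at precision/recall ≥ 0.9 under these conditions
validates the *logic* of the filter chain (thresholding, intersection,
control veto, window and intervening-gene rules), not the biology of any
particular dataset; on real data the binding-site multiplicity, peak-caller
artifacts and annotation quality dominate.

## Numerical and degenerate-input choices

* FDR boundary: strict (>), so qscore exactly 3.0 fails at t = 0.001.
* Window boundaries: inclusive at exactly −3,000 and +1,500.
* Region center: floor midpoint; even-length regions round down.
* Empty inputs: empty peak lists give empty consensus; zero assignments
  skip the enrichment test (reported as absent, not as p = 1); an empty
  target or reference set gives a degenerate-margin Fisher table and p = 1.
* Zero-width or inverted intervals are rejected at construction, as are
  summits outside their peak and q-values below 0 (including the
  narrowPeak "-1 = unavailable" sentinel, which the FDR filter cannot use).
* The pipeline's bootstrap seed is the run seed plus a stage offset; all
  seeds stay well below 2³¹.

## Problem sizes used in the test suite

Oracle-equivalence tests run 1,000 random consensus instances (≤ 5
chromosomes, ≤ 200 peaks/replicate) and 100 synthetic genomes × 500
regions against literal per-base and all-pairs reference implementations;
calibration uses 500 null datasets at B = 200 (the type-I error of the
add-one estimator is exactly ⌊0.05·201⌋/201 ≈ 0.0498 under the null, and
the test asserts the [0.03, 0.07] band); power uses 100 runs at n = 200,
B = 500; Fisher correctness enumerates all 46,376 tables with N ≤ 30.
These sizes keep the full suite under a minute apart from the enumeration
sweep, while leaving every statistical check at ≥ 3σ resolution.

## Known limitations

* Single-isoform gene models; the coding span is the union of CDS features.
* One latent site per target gene in simulation; multi-site genes are out
  of scope, so recall is defined per gene, not per site.
* The bootstrap null conditions on the *recovered* target-gene windows, as
  the original analysis does; with very few targets the null becomes
  coarse (few distinct zone fractions), which the add-one estimator
  handles conservatively.
* No fractional-overlap option for the control veto (any-base overlap
  only); no IDR-style reproducibility scoring.
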