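"""Zone classification, metagene histogram, bootstrap null, empirical test."""

import numpy as np
import pytest

from conftest import gene
from oracles import empirical_p_counts

from targetcall.annotation_io import GeneAnnotation
from targetcall.assign import TargetAssignment, assign_regions, build_windows
from targetcall.consensus import ConsensusRegion
from targetcall.annotation_io import GenomicInterval
from targetcall.enrichment import (
    ZoneCounts,
    bootstrap_null,
    classify_zone,
    enrichment_test,
    metagene_histogram,
)


def annotation(*genes, chrom_sizes=None):
    return GeneAnnotation(
        genes=list(genes), chrom_sizes=chrom_sizes or {"chr1": 1_000_000}
    )


class TestClassifyZone:
    def test_plus_strand_zones(self):
        g = gene("g1", "chr1", "+", 10000, 12000)
        assert classify_zone(9500, g) == "promoter"
        assert classify_zone(11000, g) == "transcribed"
        assert classify_zone(12500, g) == "downstream"
        assert classify_zone(6999, g) == "outside"
        assert classify_zone(13500, g) == "outside"

    def test_minus_strand_mirror(self):
        g = gene("g1", "chr1", "-", 10000, 12000)
        assert classify_zone(12500, g) == "promoter"
        assert classify_zone(11000, g) == "transcribed"
        assert classify_zone(9500, g) == "downstream"


class TestMetageneHistogram:
    def test_empty(self):
        hist = metagene_histogram([], annotation(), bin_width=100)
        assert hist.total == 0

    def test_single_upstream_offset_bins_correctly(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        a = TargetAssignment("r1", "g1", "promoter", -250)
        hist = metagene_histogram([a], ann, bin_width=100)
        assert hist.upstream_bins == {-300: 1}
        assert hist.total == 1

    def test_internal_positions_split_between_anchors(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        near_start = TargetAssignment("r1", "g1", "transcribed", 100)
        near_end = TargetAssignment("r2", "g1", "transcribed", 1900)
        hist = metagene_histogram([near_start, near_end], ann, bin_width=100)
        assert sum(hist.internal_start_bins.values()) == 1
        assert sum(hist.internal_end_bins.values()) == 1
        # end-anchored offset of position 1900 in a 2000 bp span is -99
        assert hist.internal_end_bins == {-100: 1}

    def test_total_is_conserved_on_random_assignments(self):
        rng = np.random.default_rng(2)
        genes = [
            gene(f"g{i}", "chr1", "+" if i % 2 else "-",
                 20000 * i + 10000, 20000 * i + 13000)
            for i in range(10)
        ]
        ann = annotation(*genes)
        windows = build_windows(ann)
        regions = []
        for i, c in draw_window_centers(rng, windows):
            regions.append(
                ConsensusRegion(GenomicInterval("chr1", c, c + 1), f"r{i}", ())
            )
        assignments = assign_regions(regions, ann)
        assert len(assignments) > 0
        hist = metagene_histogram(assignments, ann)
        assert hist.total == len(assignments)
        assert sum(c for *_, c in hist.rows()) == len(assignments)


def draw_window_centers(rng, windows, n=1000):
    """Random positions drawn inside the given windows."""
    out = []
    for i in range(n):
        w = windows[rng.integers(0, len(windows))]
        out.append((i, int(rng.integers(w.interval.start, w.interval.end))))
    return out


class TestBootstrapNull:
    def test_zero_observed_gives_zero_counts(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        (counts,) = bootstrap_null(ann, {"g1"}, n_observed=0, B=1, seed=0)
        assert counts.total == 0

    def test_degenerate_one_bp_anchor_is_nearly_all_promoter(self):
        """With a 1 bp anchor and downstream_bp=0 the window is 3000 bp of
        promoter plus the single anchor base."""
        g = gene("g1", "chr1", "+", 50000, 50001)
        ann = annotation(g)
        null = bootstrap_null(
            ann, {"g1"}, n_observed=1000, B=5, seed=1, downstream_bp=0
        )
        for counts in null:
            assert counts.downstream == 0
            assert counts.promoter >= 990  # 3000/3001 of the window

    def test_counts_conserve_n_observed(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        null = bootstrap_null(ann, {"g1"}, n_observed=57, B=50, seed=3)
        assert all(c.total == 57 for c in null)

    def test_fractions_match_base_composition(self):
        """Zone frequencies over one gene converge to the window's exact
        base composition (3000 / 2000 / 1500 of 6500) within 3 SE."""
        ann = annotation(gene("g1", "chr1", "-", 10000, 12000))
        n = 10_000
        (counts,) = bootstrap_null(ann, {"g1"}, n_observed=n, B=1, seed=4)
        for zone, frac in (
            ("promoter", 3000 / 6500),
            ("transcribed", 2000 / 6500),
            ("downstream", 1500 / 6500),
        ):
            se = (frac * (1 - frac) / n) ** 0.5
            assert abs(counts.fraction(zone) - frac) <= 3 * se

    def test_deterministic_and_validates_inputs(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        a = bootstrap_null(ann, {"g1"}, 10, B=5, seed=9)
        b = bootstrap_null(ann, {"g1"}, 10, B=5, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            bootstrap_null(ann, set(), 10, B=5, seed=0)
        with pytest.raises(ValueError):
            bootstrap_null(ann, {"nope"}, 10, B=5, seed=0)


class TestEnrichmentTest:
    def test_observed_above_all_null_hits_floor(self):
        observed = ZoneCounts(90, 5, 5)
        null = [ZoneCounts(10, 80, 10) for _ in range(99)]
        res = {r.zone: r for r in enrichment_test(observed, null)}
        assert res["promoter"].p_enriched == 1 / 100
        assert res["promoter"].p_depleted == 1.0
        assert res["promoter"].direction == "enriched"

    def test_all_null_equal_observed_gives_p_one(self):
        observed = ZoneCounts(30, 50, 20)
        null = [ZoneCounts(30, 50, 20) for _ in range(200)]
        for r in enrichment_test(observed, null):
            assert r.p_enriched == 1.0 and r.p_depleted == 1.0
            assert r.direction == "neither"

    def test_matches_counting_oracle_on_seeded_case(self):
        rng = np.random.default_rng(77)
        observed = ZoneCounts(40, 35, 25)
        null = [
            ZoneCounts(*(int(x) for x in rng.multinomial(100, [0.4, 0.35, 0.25])))
            for _ in range(200)
        ]
        results = enrichment_test(observed, null)
        for r in results:
            fracs = [c.fraction(r.zone) for c in null]
            p_enr, p_dep = empirical_p_counts(observed.fraction(r.zone), fracs)
            assert r.p_enriched == pytest.approx(p_enr, abs=0)
            assert r.p_depleted == pytest.approx(p_dep, abs=0)

    def test_p_values_never_zero_and_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            observed = ZoneCounts(*(int(x) for x in rng.multinomial(50, [1/3]*3)))
            null = [
                ZoneCounts(*(int(x) for x in rng.multinomial(50, [1/3]*3)))
                for _ in range(37)
            ]
            for r in enrichment_test(observed, null):
                assert 1 / 38 <= r.p_enriched <= 1.0
                assert 1 / 38 <= r.p_depleted <= 1.0

    def test_requires_nonempty_inputs(self):
        with pytest.raises(ValueError):
            enrichment_test(ZoneCounts(1, 1, 1), [])
        with pytest.raises(ValueError):
            enrichment_test(ZoneCounts(0, 0, 0), [ZoneCounts(1, 0, 0)])
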