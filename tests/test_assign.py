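"""Peak-to-gene assignment: windows, boundaries, intervening-gene veto."""

import numpy as np
import pytest

from conftest import gene
from oracles import brute_force_assignments

from targetcall.annotation_io import GeneAnnotation, GenomicInterval
from targetcall.assign import (
    assign_region,
    assign_regions,
    build_windows,
    target_gene_set,
)
from targetcall.consensus import ConsensusRegion
from targetcall.simulate import SimulationParams, simulate_genome


def region_at(center, chrom="chr1", width=10, rid="r1"):
    return ConsensusRegion(
        interval=GenomicInterval(chrom, center - width // 2, center - width // 2 + width),
        region_id=rid,
        support=(("rep1", "p"),),
    )


def annotation(*genes, chrom_sizes=None):
    return GeneAnnotation(
        genes=list(genes), chrom_sizes=chrom_sizes or {"chr1": 1_000_000}
    )


class TestBuildWindows:
    def test_plus_strand_window(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        (w,) = build_windows(ann)
        assert (w.interval.start, w.interval.end) == (7000, 13500)

    def test_minus_strand_mirror(self):
        ann = annotation(gene("g1", "chr1", "-", 10000, 12000))
        (w,) = build_windows(ann)
        assert (w.interval.start, w.interval.end) == (8500, 15000)

    def test_clipped_at_chromosome_start(self):
        ann = annotation(gene("g1", "chr1", "+", 500, 900))
        (w,) = build_windows(ann)
        assert (w.interval.start, w.interval.end) == (0, 2400)

    def test_coding_anchor_uses_cds(self):
        ann = annotation(gene("g1", "chr1", "+", 9000, 13000, 10000, 12000))
        (w,) = build_windows(ann, anchor="coding")
        assert (w.interval.start, w.interval.end) == (7000, 13500)
        (w,) = build_windows(ann, anchor="transcript")
        assert (w.interval.start, w.interval.end) == (6000, 14500)


class TestAssignRegion:
    def test_promoter_assignment_with_offset(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        windows = build_windows(ann)
        (a,) = assign_region(region_at(9000), windows, ann)
        assert (a.gene_id, a.zone, a.offset) == ("g1", "promoter", -1000)

    def test_intervening_gene_vetoes(self):
        """A second gene's transcribed span wholly between the center and
        the candidate's coding start removes the candidate assignment."""
        g1 = gene("g1", "chr1", "+", 10000, 12000)
        blocker = gene("g2", "chr1", "+", 8000, 8500)
        ann = annotation(g1, blocker)
        windows = build_windows(ann)
        got = assign_region(region_at(7500), windows, ann)
        assert all(a.gene_id != "g1" for a in got)
        # without the blocker, g1 is assigned
        ann2 = annotation(g1)
        got2 = assign_region(region_at(7500), build_windows(ann2), ann2)
        assert [a.gene_id for a in got2] == ["g1"]

    def test_window_boundary_inclusive_at_3000(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        windows = build_windows(ann)
        at_edge = assign_region(region_at(7000), windows, ann)
        assert [a.offset for a in at_edge] == [-3000]
        beyond = assign_region(region_at(6999), windows, ann)
        assert beyond == []

    def test_downstream_boundary_inclusive_at_1500(self):
        ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
        windows = build_windows(ann)
        at_edge = assign_region(region_at(13499), windows, ann)
        assert [(a.zone, a.offset) for a in at_edge] == [("downstream", 1500)]
        assert assign_region(region_at(13500), windows, ann) == []

    def test_divergent_promoter_double_assignment(self):
        left = gene("gL", "chr1", "-", 5000, 7000)    # promoter to the right
        right = gene("gR", "chr1", "+", 11000, 13000)  # promoter to the left
        ann = annotation(left, right)
        windows = build_windows(ann)
        got = assign_region(region_at(9000), windows, ann)
        assert {(a.gene_id, a.zone) for a in got} == {
            ("gL", "promoter"), ("gR", "promoter")
        }

    def test_transcribed_center_needs_no_intervening_check(self):
        # a nested gene inside the candidate's span must not veto
        host = gene("host", "chr1", "+", 10000, 20000)
        nested = gene("nested", "chr1", "+", 12000, 13000)
        ann = annotation(host, nested)
        windows = build_windows(ann)
        got = assign_region(region_at(15000), windows, ann)
        assert ("host", "transcribed") in {(a.gene_id, a.zone) for a in got}


class TestStrandSymmetry:
    def test_mirrored_genome_gives_mirrored_assignments(self):
        size = 1_000_000
        genes = [
            gene("a", "chr1", "+", 10000, 12000),
            gene("b", "chr1", "-", 20000, 23000),
            gene("c", "chr1", "+", 26000, 27000),
        ]
        ann = annotation(*genes, chrom_sizes={"chr1": size})

        def mirror_gene(g):
            flip = {"+": "-", "-": "+"}
            return gene(
                g.gene_id, "chr1", flip[g.strand],
                size - g.tx_span.end, size - g.tx_span.start,
            )

        mirrored = annotation(*[mirror_gene(g) for g in genes],
                              chrom_sizes={"chr1": size})
        rng = np.random.default_rng(0)
        for center in rng.integers(5000, 40000, size=200):
            center = int(center)
            fwd = assign_region(region_at(center), build_windows(ann), ann)
            # mirrored center: position p maps to size-1-p
            rev = assign_region(
                region_at(size - 1 - center), build_windows(mirrored), mirrored
            )
            assert {(a.gene_id, a.zone, a.offset) for a in fwd} == {
                (a.gene_id, a.zone, a.offset) for a in rev
            }


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_scan_on_synthetic_genomes(self, seed):
        params = SimulationParams(
            seed=seed, n_genes=120, n_true_targets=10, n_chroms=2,
            ref_set_size=10, ref_overlap=5,
        )
        ann = simulate_genome(params)
        rng = np.random.default_rng(1000 + seed)
        regions = []
        centers = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 3)}"
            c = int(rng.integers(100, ann.chrom_sizes[chrom] - 100))
            regions.append(region_at(c, chrom=chrom, rid=f"r{i}"))
            centers.append((f"r{i}", regions[-1].center, chrom))
        got = {
            (a.region_id, a.gene_id, a.zone, a.offset)
            for a in assign_regions(regions, ann)
        }
        assert got == brute_force_assignments(centers, ann)


class TestMonotonicity:
    def test_removing_other_genes_never_loses_assignments(self):
        g1 = gene("g1", "chr1", "+", 10000, 12000)
        blocker = gene("g2", "chr1", "+", 8000, 8500)
        third = gene("g3", "chr1", "-", 30000, 32000)
        full = annotation(g1, blocker, third)
        reduced = annotation(g1, third)
        rng = np.random.default_rng(5)
        for center in rng.integers(5000, 35000, size=300):
            r = region_at(int(center))
            with_all = {
                a.gene_id for a in assign_region(r, build_windows(full), full)
                if a.gene_id != "g2"
            }
            without = {
                a.gene_id for a in assign_region(r, build_windows(reduced), reduced)
            }
            assert with_all <= without


def test_target_gene_set_dedupes_and_sorts():
    ann = annotation(gene("g1", "chr1", "+", 10000, 12000))
    windows = build_windows(ann)
    a1 = assign_region(region_at(9000, rid="r1"), windows, ann)
    a2 = assign_region(region_at(9500, rid="r2"), windows, ann)
    assert target_gene_set(a1 + a2) == ["g1"]
    assert target_gene_set([]) == []
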