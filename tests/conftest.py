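import pytest

from targetcall.annotation_io import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    ScoredPeak,
)


def peak(chrom, start, end, peak_id="p", qscore=5.0, summit=None):
    return ScoredPeak(
        interval=GenomicInterval(chrom, start, end),
        peak_id=peak_id,
        qscore=qscore,
        summit_offset=summit,
    )


def gene(gene_id, chrom, strand, tx_start, tx_end, cds_start=None, cds_end=None):
    tx = GenomicInterval(chrom, tx_start, tx_end)
    cds = GenomicInterval(
        chrom,
        tx_start if cds_start is None else cds_start,
        tx_end if cds_end is None else cds_end,
    )
    return GeneModel(gene_id, chrom, strand, tx, cds)


@pytest.fixture
def single_gene_annotation():
    """One + strand gene, cds [10000, 12000), on a 100 kb chromosome."""
    return GeneAnnotation(
        genes=[gene("g1", "chr1", "+", 10000, 12000)],
        chrom_sizes={"chr1": 100_000},
    )
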