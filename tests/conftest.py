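import pytest

from lncpair.annotation_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)


def make_tx(tid, chrom, strand, exon_coords, gene_id=None, biotype="unknown"):
    """Compact transcript builder: exon_coords = [(start, end), ...]."""
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords),
        biotype=biotype,
    )


def make_ann(*transcripts):
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return GenomeAnnotation(
        GeneModel(gene_id=g, transcripts=ts) for g, ts in by_gene.items()
    )


@pytest.fixture
def simple_ann():
    """One coding gene on each strand plus one annotated lncRNA."""
    return make_ann(
        make_tx("cod1.t1", "chr1", "+", [(1000, 1400), (2000, 2400)],
                gene_id="cod1", biotype="coding"),
        make_tx("cod2.t1", "chr1", "-", [(10000, 10500), (12000, 12500)],
                gene_id="cod2", biotype="coding"),
        make_tx("known_lnc", "chr2", "+", [(500, 800), (1200, 1500)],
                gene_id="known_lnc_g", biotype="annotated_lncRNA"),
    )
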