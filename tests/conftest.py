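import pytest

from spliceclip.genome_io import GeneModel, GenomicInterval, Transcript


def make_transcript(tid, gid, chrom, strand, exons, cds=None):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    cds_iv = GenomicInterval(chrom, cds[0], cds[1], strand) if cds else None
    return Transcript(tid, gid, ivs, cds_iv)


@pytest.fixture
def toy_gene():
    """A plus-strand three-exon gene with CDS and both UTRs.

    Exons [100,200), [300,400), [500,600); CDS [150,550).
    """
    t = make_transcript(
        "t1", "g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)], cds=(150, 550)
    )
    return GeneModel("g1", (t,))


@pytest.fixture
def toy_gene_minus():
    t = make_transcript(
        "t1m", "g1m", "chr1", "-", [(100, 200), (300, 400), (500, 600)], cds=(150, 550)
    )
    return GeneModel("g1m", (t,))


@pytest.fixture(scope="session")
def synthetic_genes():
    """One seeded gene set covering all ten AS types (shared, read-only)."""
    from spliceclip.synthetic import make_gene_models

    return make_gene_models(10, seed=42)
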