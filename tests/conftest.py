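import pytest
from hypothesis import settings, HealthCheck

from startpipe.io_formats import GeneRecord, GenomeAnnotation
from startpipe.synthetic_data import SimConfig, simulate_all

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Three small genes on one 10 kb chromosome, one on the minus strand.

    gA: + strand, exons [1000,1200) and [1500,1800), 3'UTR [1700,1800)
    gB: - strand, exons [3000,3300) and [3600,3900)  (TSS at 3899)
    gC: + strand, single exon [6000,7000), no introns
    """
    genes = [
        GeneRecord(gene_id="gA", chrom="chr1", strand="+", span=(1000, 1800),
                   transcripts=[("gA.t1", [(1000, 1200), (1500, 1800)])],
                   utr3=(1700, 1800)),
        GeneRecord(gene_id="gB", chrom="chr1", strand="-", span=(3000, 3900),
                   transcripts=[("gB.t1", [(3000, 3300), (3600, 3900)])],
                   utr3=(3000, 3100)),
        GeneRecord(gene_id="gC", chrom="chr1", strand="+", span=(6000, 7000),
                   transcripts=[("gC.t1", [(6000, 7000)])],
                   utr3=(6900, 7000)),
    ]
    ann = GenomeAnnotation(chrom_sizes={"chr1": 10_000}, genes=genes)
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def default_sim():
    """One full simulation at the default study scale, shared across tests."""
    config = SimConfig(seed=11)
    return config, simulate_all(config)


def mirror_annotation(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Reflect every coordinate (pos -> L-1-pos) and flip every strand."""
    genes = []
    for g in ann.genes:
        L = ann.chrom_sizes[g.chrom]

        def m(iv):
            return (L - iv[1], L - iv[0])

        txs = [(tid, sorted(m(e) for e in exons)) for tid, exons in g.transcripts]
        genes.append(GeneRecord(
            gene_id=g.gene_id, chrom=g.chrom,
            strand="-" if g.strand == "+" else "+",
            span=m(g.span), transcripts=txs,
            utr3=m(g.utr3) if g.utr3 else None))
    out = GenomeAnnotation(chrom_sizes=dict(ann.chrom_sizes), genes=genes)
    out.validate()
    return out
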