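import pytest

from ethylome import synthetic
from ethylome.types import Annotation, Gene, TranscriptModel

#: the three-exon reference used throughout the splice-event examples
REF3 = ((0, 100), (200, 300), (400, 500))


def make_gene(gid="geneA", chrom="chr1", strand="+", exons=REF3):
    g = Gene(id=gid, chrom=chrom, strand=strand,
             start=exons[0][0], end=exons[-1][1])
    g.transcripts.append(
        TranscriptModel(id=f"{gid}.t1", chrom=chrom, strand=strand, exons=exons)
    )
    return g


@pytest.fixture(scope="session")
def toy_genome():
    return synthetic.generate_genome(11, n_chrom=2, chrom_length=60_000,
                                     gc_fraction=0.4)


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return synthetic.generate_annotation(toy_genome, 12, n_genes=40,
                                         intergenic_gap=400)


@pytest.fixture()
def mini_annotation():
    """Two genes on chr1 (one per strand) for hand-computed examples."""
    return Annotation([
        make_gene("geneA", strand="+", exons=REF3),
        make_gene("geneB", strand="-", exons=((5000, 5200), (5400, 5600))),
    ])
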