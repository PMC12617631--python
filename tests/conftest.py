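import pytest

from fixiscan.records import GeneRecord, Strand


def make_contig(strands, genome="G1", contig="c1", labels=None, start0=1, gene_len=900, gap=100):
    """Build a rank-ordered contig from a strand string like '++-+'.

    labels: optional dict rank -> iterable of marker labels.
    """
    labels = labels or {}
    genes = []
    for rank, s in enumerate(strands):
        start = start0 + rank * (gene_len + gap)
        genes.append(
            GeneRecord(
                genome_id=genome,
                contig_id=contig,
                rank=rank,
                gene_id=f"{genome}_{contig}_g{rank}",
                start=start,
                end=start + gene_len - 1,
                strand=Strand.FORWARD if s == "+" else Strand.REVERSE,
                protein_id=f"P_{genome}_{contig}_g{rank}",
                labels=frozenset(labels.get(rank, ())),
            )
        )
    return genes


@pytest.fixture
def contig_factory():
    return make_contig
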