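import pytest

from k27pipe.io_formats import Gene, GenomicInterval
from k27pipe.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One fully simulated study (seed 1, study-default conditions), shared
    across tests that only read from it."""
    return simulate_all(SimulationConfig(seed=1))


def make_gene(gene_id="g1", chrom="A01", start=1000, end=2000, strand="+",
              exons=None, **kw):
    locus = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        mid = (start + end) // 2
        exons = [(start, mid - 100), (mid, end)]
    exon_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return Gene(gene_id, locus, exon_ivs, **kw)
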