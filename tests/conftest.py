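import numpy as np
import pytest

from mitoarch.genome_io import FeatureAnnotation, GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def simple_genome():
    """1 kb circular genome: one 600 bp gene at [100,700), rest intergenic."""
    seq = "AT" * 500
    gene = FeatureAnnotation(kind="gene_exon", gene_name="cox2", strand="+",
                             intervals=((100, 700),))
    return GenomeRecord(id="toy", sequence=seq, topology="circular", features=[gene])


def random_dna(rng, n, gc=0.25):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
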