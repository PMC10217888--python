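import numpy as np
import pytest

from genomecut.model import AnnotatedGenome, GeneRecord
from genomecut.simulate import gen_genome


def make_genome_from_labels(labels, gene_len=100, gap=10, seq_char_len=None):
    """Tiny genome with abutting-ish genes carrying the given labels."""
    genes = []
    cursor = 0
    for i, lab in enumerate(labels):
        start = cursor + gap
        genes.append(GeneRecord(f"G_{i:04d}", start, start + gene_len, "+", lab))
        cursor = start + gene_len
    total = seq_char_len or cursor + gap
    rng = np.random.default_rng(1234)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, total)])
    return AnnotatedGenome(chrom_id="test", sequence=seq, genes=genes, circular=False)


@pytest.fixture(scope="session")
def small_genome():
    """A ~60 kb genome with two planted >10 kb nonessential regions."""
    genome, truth = gen_genome(n_genes=50, region_size_targets=[12000, 11000], seed=11)
    return genome, truth


@pytest.fixture(scope="session")
def design_genome():
    """A genome with mid-size planted regions for construct design tests."""
    genome, truth = gen_genome(
        n_genes=40, region_size_targets=[4000, 4500, 5000], seed=7
    )
    return genome, truth
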