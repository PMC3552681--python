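import numpy as np
import pytest

from paraconserve.seqio import GeneRecord, GeneType, Strand
from paraconserve.synthetic import SimulationConfig, generate_dataset


def make_gene(gene_id, genome_id, sequence, gene_type=GeneType.PROTEIN,
              start_pos=1):
    return GeneRecord(gene_id=gene_id, genome_id=genome_id,
                      gene_type=gene_type, strand=Strand.FORWARD,
                      start_pos=start_pos, sequence=sequence)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared across tests (6 genomes, 6 families)."""
    cfg = SimulationConfig(n_genomes=6, n_families=6, protein_length=80,
                           seq_length=600, n_decoys=2, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
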