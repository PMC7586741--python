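import pandas as pd
import pytest

from crunmark.config import PipelineConfig, SimulationConfig
from crunmark.fragments import FragmentSet
from crunmark.synthetic_data import (
    generate_annotation,
    generate_toy_genome,
)


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(n_contigs=10, mean_len=20_000, seed=7)


@pytest.fixture(scope="session")
def toy_genome_seq():
    return generate_toy_genome(n_contigs=5, mean_len=5_000, seed=11, with_sequences=True)


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return generate_annotation(toy_genome, n_genes=20, gene_len=2000, seed=7)


@pytest.fixture()
def tiny_fragments():
    """Hand-sized fragment set on a single contig for exact checks."""
    df = pd.DataFrame(
        {
            "contig": ["c1"] * 4,
            "start": [0, 490, 600, 900],
            "end": [100, 510, 700, 1200],
        }
    )
    return FragmentSet("tiny", df)


@pytest.fixture(scope="session")
def small_config():
    """A fast end-to-end configuration for pipeline-level tests."""
    sim = SimulationConfig(
        n_contigs=20,
        mean_contig_len=15_000,
        n_genes=40,
        samples=("EC_Ni", "NEC_Ni"),
        marked_per_sample=8,
        n_tissues=6,
        n_specific=10,
        n_broad=10,
        n_go_terms=12,
        n_planted_terms=1,
    )
    return PipelineConfig(seed=3, simulation=sim)
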