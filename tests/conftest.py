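import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mobilnc import SimConfig, run_pipeline
from mobilnc.simulate import generate_genome_pair


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact error-free experiment exercised by many truth-recovery tests."""
    return SimConfig(
        seed=101,
        genome_length_per_species=200_000,
        n_genes_per_species=12,
        n_lncrnas_per_species=8,
        n_read_pairs_per_tissue=2_000,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_run(small_cfg):
    return run_pipeline(small_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Error-free, fully spliced reads: fragment counts must equal truth."""
    return SimConfig(
        seed=202,
        genome_length_per_species=200_000,
        n_genes_per_species=10,
        n_lncrnas_per_species=6,
        n_read_pairs_per_tissue=1_500,
        unspliced_read_fraction=0.0,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_run(clean_cfg):
    return run_pipeline(clean_cfg)


@pytest.fixture(scope="session")
def lnc1000_genomes():
    """Genome pair with 1000 lncRNA loci per species (2000 in total), for
    distributional checks on the generator."""
    cfg = SimConfig(
        seed=1,
        genome_length_per_species=3_500_000,
        n_genes_per_species=0,
        n_lncrnas_per_species=1000,
    )
    return cfg, generate_genome_pair(cfg)
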