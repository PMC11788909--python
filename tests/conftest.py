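from pathlib import Path

import pytest
from hypothesis import settings

from capkin import SimConfig, simulate_dataset

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 4-family / 20-individual design at desk scale."""
    return SimConfig(
        n_provenances=2,
        families_per_provenance=2,
        offspring_per_family=5,
        n_genes=25,
        gene_length_bp=600,
        n_snps=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def cascade_vcf() -> Path:
    """Hand-built 10-locus VCF violating one filter rule per designed locus."""
    return DATA_DIR / "filter_cascade.vcf"
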