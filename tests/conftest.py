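import logging

import numpy as np
import pytest

from spliceworks.dataprep import SplitSpec, create_datasets
from spliceworks.fixtures import FixtureSpec, generate_genome, generate_vcf, make_mock_scorer

logging.getLogger("spliceworks").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def genome(tmp_path_factory):
    """The standard desk-scale synthetic genome, written to disk once."""
    return generate_genome(FixtureSpec(), tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def mock_scorer():
    return make_mock_scorer()


@pytest.fixture(scope="session")
def tiny_datasets(genome, tmp_path_factory):
    """Train/test archives at the tiny 32-nt flanking configuration."""
    out = tmp_path_factory.mktemp("datasets")
    return create_datasets(
        genome.fasta_path, genome.gff_path, out,
        split=SplitSpec(method="human"), flank=32,
    )


@pytest.fixture(scope="session")
def fixture_vcf(genome, tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "variants.vcf"
    records = generate_vcf(genome, path, seed=10)
    return path, records


@pytest.fixture()
def rng():
    return np.random.default_rng(10)
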