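import numpy as np
import pytest

from l1exapt.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small synthetic study for fast unit tests."""
    return SyntheticConfig(
        copies_per_subfamily=40, n_chroms=2, chrom_len=700_000
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_config):
    outdir = tmp_path_factory.mktemp("tiny_dataset")
    return generate_dataset(outdir, seed=7, config=tiny_config)


@pytest.fixture(scope="session")
def small_fasta(tmp_path_factory):
    """Two-chromosome toy genome with known sequence."""
    path = tmp_path_factory.mktemp("fasta") / "toy.fa"
    path.write_text(">chrT\nACGTACGT\n>chrU\nAAAACCCC\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
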