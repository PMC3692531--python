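import pytest

from acetylmap.synth import SyntheticConfig, generate_dataset, simulate_chip_tags


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_genes=150, chrom_length=1_400_000, n_chroms=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def wt_tags(small_dataset):
    return simulate_chip_tags(small_dataset, "H3K9ac-WT")


@pytest.fixture(scope="session")
def rnai_tags(small_dataset):
    return simulate_chip_tags(small_dataset, "H3K9ac-RNAi")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_dataset):
    """The synthetic fixture written to disk once per session."""
    from acetylmap.synth import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, outdir)
    return outdir
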