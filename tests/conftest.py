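import pytest

from gasreg.simulate import FixtureConfig, generate_fixture

# 19-mer printed as the Il2ra enhancer fragment; contains exactly one GAS window
IL2RA_FRAGMENT = "GTTTCTTCTGAGAAGTACC"

SMALL_FIXTURE_KWARGS = dict(
    genome_bp=400_000,
    n_tf_peaks=400,
    n_genes=40,
    n_planted_clusters=4,
    n_deg_up=12,
)


def small_config(seed: int = 3, **overrides) -> FixtureConfig:
    kwargs = {**SMALL_FIXTURE_KWARGS, **overrides}
    return FixtureConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(small_config(), out)


@pytest.fixture(scope="session")
def small_genome(small_fixture):
    from gasreg.core_io import read_fasta

    return read_fasta(small_fixture.genome_fa)
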