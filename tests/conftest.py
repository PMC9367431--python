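import pytest

from genomesurvey import simulate


@pytest.fixture(scope="session")
def mito_fixture():
    return simulate.make_mito_fixture(seed=0)


@pytest.fixture(scope="session")
def small_genome():
    """50 kb homozygous repeat-free genome with 20x error-free reads."""
    params = simulate.SimParams(
        genome_length=50_000, het_rate=0.0, repeat_fraction=0.0, seed=100
    )
    genome = simulate.simulate_diploid_genome(params)
    reads = simulate.simulate_reads(
        genome, coverage=20, read_length=100, error_rate=0.0, seed=101
    )
    return genome, reads
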