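import pytest
from hypothesis import settings

from chromolink import simulate as sim
from chromolink.pipeline import fixture_replay

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    return sim.fixture_genome(1)


@pytest.fixture(scope="session")
def fixture_plan(toy_genome):
    return sim.chromothripsis_fixture(toy_genome)


@pytest.fixture(scope="session")
def replay():
    """Error-free fixture replay at x20 coverage (seed-fixed)."""
    return fixture_replay(genome_seed=1, read_seed=1)


@pytest.fixture(scope="session")
def noisy_replay():
    """Fixture replay at 5% total error with the noisy preset."""
    return fixture_replay(
        genome_seed=1, read_seed=2, sub_rate=0.03, ins_rate=0.01, del_rate=0.01
    )
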