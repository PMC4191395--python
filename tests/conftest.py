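import pytest
from hypothesis import settings

from endmap import simulate_direct_entry_experiment, simulate_trimming_experiment

settings.register_profile("endmap", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("endmap")


@pytest.fixture(scope="session")
def direct_entry_exp():
    """One medium-sized paired in vitro / in vivo experiment, shared."""
    return simulate_direct_entry_experiment(11, n_reads=100_000)


@pytest.fixture(scope="session")
def trimming_exp():
    return simulate_trimming_experiment(7)
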