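import pytest

from ptsevo import synthetic_data
from ptsevo.vocab import Vocabulary


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary.default()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared by read-only tests."""
    return synthetic_data.sim_genome(synthetic_data.default_simspec(11))
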