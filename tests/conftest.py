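import numpy as np
import pytest
from hypothesis import settings

from primerval import simulate

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    """Default desk-scale synthetic study: (truth, pairs, alignment, truth_record)."""
    truth, pairs = simulate.default_scenario(seed=1)
    aln, record = simulate.generate_alignment(truth)
    return truth, pairs, aln, record


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
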