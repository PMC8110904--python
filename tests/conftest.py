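import numpy as np
import pytest

from isocurate.simulate import make_truth_set, simulate_reads


@pytest.fixture(scope="session")
def truth():
    """Small planted truth set shared by classifier/pipeline tests."""
    return make_truth_set(seed=11, n_genes=16)


@pytest.fixture(scope="session")
def reads(truth):
    return simulate_reads(truth, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
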