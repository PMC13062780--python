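import numpy as np
import pytest

from lockseq.seq import random_dna
from lockseq.studies import demo_project


@pytest.fixture(scope="session")
def project():
    """One shared synthetic knock-in project for pipeline-level tests."""
    return demo_project(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_target(rng):
    return random_dna(rng, 10000)
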