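import numpy as np
import pytest

from caadex import reference_genome, build_two_compartment


@pytest.fixture(scope="session")
def ref_genome():
    return reference_genome()


@pytest.fixture(scope="session")
def ref_tree(ref_genome):
    return build_two_compartment(ref_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
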