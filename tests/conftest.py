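import numpy as np
import pytest

import bmmlr


@pytest.fixture(scope="session")
def space2():
    return bmmlr.build_joint_response_space(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated trial: 4 clusters, 6 subjects per arm per cluster."""
    return bmmlr.generate_dataset(bmmlr.Scenario(J=4, n_j=6), seed=7)


@pytest.fixture(scope="session")
def table1_intercept_phi():
    """Joint probabilities implied by the true intercepts in the control arm
    at covariate 0, frozen from direct evaluation of the softmax link."""
    return np.array([0.1967051, 0.3032949, 0.3032949, 0.1967051])
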