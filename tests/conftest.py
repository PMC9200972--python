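import numpy as np
import pytest

import ichcea


@pytest.fixture(scope="session")
def inputs1():
    return ichcea.default_inputs("cohort1")


@pytest.fixture(scope="session")
def inputs2():
    return ichcea.default_inputs("cohort2")


@pytest.fixture(scope="session")
def inputs3():
    return ichcea.default_inputs("cohort3")


@pytest.fixture(scope="session")
def mis_default():
    return ichcea.MisStrategySpec()


@pytest.fixture()
def uniform_dist():
    return np.full(7, 1.0 / 7.0)
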