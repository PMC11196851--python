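import numpy as np
import pytest

from invlindley import CensoringPlan, load_fixture


@pytest.fixture(scope="session")
def rme_full():
    return load_fixture("rme_full")


@pytest.fixture(scope="session")
def art_full():
    return load_fixture("art_act_full")


@pytest.fixture(scope="session")
def rme_s1():
    return load_fixture("rme_S1")


@pytest.fixture(scope="session")
def art_s1():
    return load_fixture("art_S1")


@pytest.fixture
def small_plan():
    """A small feasible design used by the simulator tests."""
    return CensoringPlan(n=40, m=20, scheme=(5, 5, 5, 5), tau=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)
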