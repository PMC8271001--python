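import numpy as np
import pytest

from numgeo import CohortConfig, LatentChild, ProtocolConfig, simulate_cohort


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def small_cohort_data():
    """One simulated reference-style cohort (n=49, fixed seed), shared."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_child(
    s_num: float = 4.0,
    g_geo: float = 0.0,
    f_formal: float = 0.0,
    v_verbal: float = 12.0,
    age: float = 9.5,
    grade: int = 4,
    child_id: str = "c001",
) -> LatentChild:
    return LatentChild(
        child_id=child_id,
        age=age,
        grade=grade,
        s_num=s_num,
        g_geo=g_geo,
        f_formal=f_formal,
        v_verbal=v_verbal,
    )


@pytest.fixture
def child_factory():
    return make_child
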