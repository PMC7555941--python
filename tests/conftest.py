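import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uedopt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def u17():
    return uedopt.builtin_u17_8()


@pytest.fixture(scope="session")
def factors8():
    return uedopt.default_factors()


@pytest.fixture(scope="session")
def plan6():
    return uedopt.builtin_plan_table6()


@pytest.fixture(scope="session")
def table7():
    return uedopt.builtin_responses_table7()


def random_utype(rng: np.random.Generator, n: int, s: int) -> uedopt.UniformDesignTable:
    """Seeded random U-type table: each column an independent permutation."""
    entries = np.column_stack([rng.permutation(n) + 1 for _ in range(s)])
    return uedopt.UniformDesignTable(entries=entries)
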