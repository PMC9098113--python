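import numpy as np
import pytest

from lambdakit.toy_systems import (
    FixtureSpec,
    generate_fixture,
    two_substituent_system,
)


@pytest.fixture(scope="session")
def equal_k_system():
    """Two substituents, equal stiffness, ddg_bind(B) = 1.0 exactly."""
    return two_substituent_system(ddg_bind=1.0, dg_solution=-0.25)


@pytest.fixture(scope="session")
def jittered_fixture():
    """Two substituents with unequal stiffness and offset minima;
    ddg_bind(B) = 1.0 exactly by construction."""
    spec = FixtureSpec(
        ddg_bind=((1.0,),),
        dg_solution=((-0.25,),),
        k=2.0,
        jitter=0.25,
        x0_spread=0.3,
    )
    return generate_fixture(spec, seed=7)


@pytest.fixture(scope="session")
def symmetric_system():
    """Two identical substituents (ΔG = 0 everywhere)."""
    return two_substituent_system(ddg_bind=0.0, dg_solution=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
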