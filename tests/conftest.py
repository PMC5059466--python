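import numpy as np
import pytest

from atnsim.community import (Community, ParameterSet, SamplingConfig,
                              build_food_web)
from atnsim.fixtures import tiny_community
from atnsim.rates import NutrientParameters, build_rate_cache


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cfg():
    return SamplingConfig()


@pytest.fixture
def tiny():
    """Fixed 3-plant / 3-animal web with pinned constants."""
    return tiny_community()


@pytest.fixture
def tiny_cache(tiny):
    community, p, _ = tiny
    return build_rate_cache(community, p)


def make_random_web(rng, S_P=5, S_A=8, eps=0.01):
    """Random community + defaults, for property tests."""
    from atnsim.community import sample_body_masses
    cfg = SamplingConfig()
    community = sample_body_masses(S_P, S_A, cfg, rng)
    p = ParameterSet()
    community = build_food_web(community, eps=eps, R_opt=p.R_opt, gamma=p.gamma)
    nutrients = NutrientParameters(
        S=np.array([10.0, 8.0]),
        K=rng.uniform(0.1, 0.2, size=(S_P, 2)),
    )
    return community, p, nutrients
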