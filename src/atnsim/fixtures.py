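"""Small deterministic communities for tests and regression checks."""

from __future__ import annotations

import numpy as np

from .community import Community, ParameterSet, build_food_web
from .rates import NutrientParameters

__all__ = ["tiny_community"]


def tiny_community() -> tuple[Community, ParameterSet, NutrientParameters]:
    """A fixed 3-plant / 3-animal chain-plus-omnivory web.

    Masses are placed so that each plant has at least one consumer at an
    efficient ratio and the two larger animals form a short predator chain.
    All sampled constants are pinned to their distribution means.
    """
    community = Community(
        masses_plants=np.array([1.0, 10.0, 100.0]),
        masses_animals=np.array([1.0e2, 1.0e4, 1.0e6]),
    )
    p = ParameterSet()
    community = build_food_web(community, eps=0.01, R_opt=p.R_opt, gamma=p.gamma)
    nutrients = NutrientParameters(
        S=np.array([10.0, 10.0]),
        K=np.array([[0.10, 0.15], [0.12, 0.18], [0.14, 0.11]]),
        D=0.25,
    )
    return community, p, nutrients
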