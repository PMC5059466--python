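"""Right-hand side of the coupled animal-plant-nutrient differential system.

Animals gain biomass from assimilated consumption (plant and animal
pathways with separate conversion efficiencies), lose it to predators and
to metabolism. Plants grow by nutrient-limited uptake and lose biomass to
grazing and metabolism. The two nutrient pools relax toward their supply
concentrations and are drained by plant uptake in proportion to the
nutrient content of plant biomass.

The solver-facing entry point is :func:`rhs_flat`, which operates on a
packed state vector ``[A, P, N]`` and shares a single evaluation of the
feeding matrix and growth factors so that gain, mortality and function
accounting stay mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community, ParameterSet
from .rates import NutrientParameters, RateCache, feeding_rate_matrix, growth_factor

__all__ = [
    "State",
    "Derivative",
    "animal_derivatives",
    "plant_derivatives",
    "nutrient_derivatives",
    "rhs",
    "rhs_flat",
    "pack_state",
    "unpack_state",
]


@dataclass
class State:
    """Biomass densities plus the two nutrient concentrations at one instant."""

    A: np.ndarray
    P: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if np.any(self.A < 0) or np.any(self.P < 0) or np.any(self.N < 0):
            raise ValueError("state components must be nonnegative")
        if self.N.size != 2:
            raise ValueError("exactly two nutrients are modelled")


@dataclass
class Derivative:
    dA: np.ndarray
    dP: np.ndarray
    dN: np.ndarray


def pack_state(state: State) -> np.ndarray:
    return np.concatenate([state.A, state.P, state.N])


def unpack_state(y: np.ndarray, S_A: int, S_P: int) -> State:
    y = np.clip(y, 0.0, None)
    return State(A=y[:S_A], P=y[S_A:S_A + S_P], N=y[S_A + S_P:])


def _check_finite(state: State) -> None:
    if not (np.all(np.isfinite(state.A)) and np.all(np.isfinite(state.P))
            and np.all(np.isfinite(state.N))):
        raise ValueError("non-finite value in state")


def _core(state, community, cache, p, nutrients):
    """Shared evaluation: feeding matrix, growth factors, uptake."""
    F = feeding_rate_matrix(state.A, state.P, community, cache, p)
    G = growth_factor(state.N, nutrients.K)
    uptake = cache.r * G * state.P
    return F, G, uptake


def animal_derivatives(
    state: State,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
) -> np.ndarray:
    """dA_i = A_i (e_P * herbivory_i + e_A * carnivory_i) - predation on i - metabolism."""
    _check_finite(state)
    F = feeding_rate_matrix(state.A, state.P, community, cache, p)
    return _animal_derivatives(state, community, cache, p, F)


def _animal_derivatives(state, community, cache, p, F):
    S_P = community.S_P
    gain = p.e_P * F[:, :S_P].sum(axis=1) + p.e_A * F[:, S_P:].sum(axis=1)
    predation = F[:, S_P:].T @ state.A
    return state.A * gain - predation - cache.x_animals * state.A


def plant_derivatives(
    state: State,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    nutrients: NutrientParameters,
) -> np.ndarray:
    """dP_i = r_i G_i P_i - grazing on i - metabolism."""
    _check_finite(state)
    F, _, uptake = _core(state, community, cache, p, nutrients)
    return _plant_derivatives(state, community, cache, F, uptake)


def _plant_derivatives(state, community, cache, F, uptake):
    grazing = F[:, :community.S_P].T @ state.A
    return uptake - grazing - cache.x_plants * state.P


def nutrient_derivatives(
    state: State,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    nutrients: NutrientParameters,
) -> np.ndarray:
    """dN_l = D (S_l - N_l) - v_l * total plant uptake."""
    _check_finite(state)
    _, _, uptake = _core(state, community, cache, p, nutrients)
    return _nutrient_derivatives(state, nutrients, uptake)


def _nutrient_derivatives(state, nutrients, uptake):
    return nutrients.D * (nutrients.S - state.N) - nutrients.v * uptake.sum()


def rhs(
    state: State,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    nutrients: NutrientParameters,
) -> Derivative:
    """Full derivative with one shared evaluation of F and G per call."""
    _check_finite(state)
    if state.A.size != community.S_A or state.P.size != community.S_P:
        raise ValueError("state shape does not match community")
    F, _, uptake = _core(state, community, cache, p, nutrients)
    return Derivative(
        dA=_animal_derivatives(state, community, cache, p, F),
        dP=_plant_derivatives(state, community, cache, F, uptake),
        dN=_nutrient_derivatives(state, nutrients, uptake),
    )


def rhs_flat(
    t: float,
    y: np.ndarray,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    nutrients: NutrientParameters,
) -> np.ndarray:
    """Packed-vector right-hand side for the ODE solver.

    Slightly negative probe values from the implicit solver are clamped to
    zero for rate evaluation only; the integrated trajectory is unaffected
    at the working tolerances.
    """
    S_A, S_P = community.S_A, community.S_P
    A = np.clip(y[:S_A], 0.0, None)
    P = np.clip(y[S_A:S_A + S_P], 0.0, None)
    N = np.clip(y[S_A + S_P:], 0.0, None)

    R = np.concatenate([P, A])
    Rq = R ** (1.0 + p.q)
    omega = community.omega
    sat = cache.bh @ Rq
    if p.omega_in_denominator:
        sat = omega * sat
    denom = community.masses_animals * (1.0 + p.c * A + sat)
    F = (omega[:, None] * cache.b * Rq[None, :]) / denom[:, None]

    gain = p.e_P * F[:, :S_P].sum(axis=1) + p.e_A * F[:, S_P:].sum(axis=1)
    dA = A * gain - F[:, S_P:].T @ A - cache.x_animals * A

    G = np.min(N / (nutrients.K + N), axis=1)
    uptake = cache.r * G * P
    dP = uptake - F[:, :S_P].T @ A - cache.x_plants * P

    dN = nutrients.D * (nutrients.S - N) - nutrients.v * uptake.sum()
    return np.concatenate([dA, dP, dN])
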