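"""Ecosystem-function summaries over the stationary evaluation window.

Six community-level quantities are averaged over the sampled window grid:
total animal and plant biomass stocks (A, P), gross biomass flows from
plants to animals (F_P, herbivory) and within the animal guild (F_A,
intraguild predation) -- both before assimilation losses -- and summed
metabolic losses of the two compartments (X_A, X_P). Flows are recomputed
from the stored states rather than accumulated online.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community, ParameterSet
from .rates import RateCache, feeding_rate_matrix, metabolic_rate
from .simulator import Trajectory

__all__ = [
    "FunctionRecord",
    "window_average_stocks",
    "window_average_flows",
    "window_average_metabolism",
    "mean_individual_mass",
    "compute_function_record",
]


@dataclass
class FunctionRecord:
    S_A_init: int
    S_P_init: int
    S_A_final: int
    S_P_final: int
    A_total: float
    P_total: float
    F_P: float
    F_A: float
    X_A: float
    X_P: float
    mean_mass_animals: float    # NaN when no animal survives
    mean_mass_plants: float
    discarded: bool
    failed: bool = False
    seed: int | None = None


def _window(trajectory: Trajectory, eval_window: float) -> slice:
    t_start = trajectory.times[-1] - eval_window
    sl = trajectory.window_slice(t_start)
    if trajectory.times[sl.start] > t_start + 1e-6:
        raise ValueError("trajectory does not cover the evaluation window")
    return sl


def window_average_stocks(
    trajectory: Trajectory, eval_window: float
) -> tuple[float, float]:
    """Window means of the summed biomasses, (A_total, P_total)."""
    sl = _window(trajectory, eval_window)
    return (
        float(trajectory.A[sl].sum(axis=1).mean()),
        float(trajectory.P[sl].sum(axis=1).mean()),
    )


def window_average_flows(
    trajectory: Trajectory,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    eval_window: float,
) -> tuple[float, float]:
    """Window-mean gross flows (F_P, F_A), biomass per unit time.

    At every stored sample the feeding matrix is re-evaluated from the
    state; per-unit-biomass rates are scaled by consumer biomass and summed
    over the plant-resource and animal-resource blocks respectively.
    """
    sl = _window(trajectory, eval_window)
    S_P = community.S_P
    fp = 0.0
    fa = 0.0
    n = 0
    for A, P in zip(trajectory.A[sl], trajectory.P[sl]):
        F = feeding_rate_matrix(A, P, community, cache, p)
        flow = F * A[:, None]
        fp += flow[:, :S_P].sum()
        fa += flow[:, S_P:].sum()
        n += 1
    return float(fp / n), float(fa / n)


def window_average_metabolism(
    trajectory: Trajectory,
    community: Community,
    p: ParameterSet,
    eval_window: float,
) -> tuple[float, float]:
    """(X_A, X_P): per-biomass metabolic rates times window-mean biomasses."""
    sl = _window(trajectory, eval_window)
    A_bar = trajectory.A[sl].mean(axis=0)
    P_bar = trajectory.P[sl].mean(axis=0)
    x_a = metabolic_rate(community.masses_animals, p.x_A, p.metab_exp)
    x_p = metabolic_rate(community.masses_plants, p.x_P, p.metab_exp)
    return float(x_a @ A_bar), float(x_p @ P_bar)


def mean_individual_mass(
    mean_biomasses: np.ndarray,
    masses: np.ndarray,
    definition: str = "numbers",
) -> float:
    """Average individual body mass of one guild.

    ``numbers`` (default): total biomass over total individual density,
    ``sum(B_i) / sum(B_i / m_i)``. ``biomass``: biomass-weighted mean mass
    ``sum(m_i B_i) / sum(B_i)``. NaN if the guild has no biomass.
    """
    B = np.asarray(mean_biomasses, dtype=float)
    m = np.asarray(masses, dtype=float)
    total = B.sum()
    if total <= 0:
        return float("nan")
    if definition == "numbers":
        return float(total / (B / m).sum())
    if definition == "biomass":
        return float((m * B).sum() / total)
    raise ValueError(f"unknown definition {definition!r}")


def compute_function_record(
    trajectory: Trajectory,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
    eval_window: float,
    discarded: bool,
    seed: int | None = None,
    mass_definition: str = "numbers",
) -> FunctionRecord:
    sl = _window(trajectory, eval_window)
    A_total, P_total = window_average_stocks(trajectory, eval_window)
    F_P, F_A = window_average_flows(trajectory, community, cache, p, eval_window)
    X_A, X_P = window_average_metabolism(trajectory, community, p, eval_window)
    A_bar = trajectory.A[sl].mean(axis=0)
    P_bar = trajectory.P[sl].mean(axis=0)
    return FunctionRecord(
        S_A_init=community.S_A,
        S_P_init=community.S_P,
        S_A_final=int(np.count_nonzero(trajectory.A[-1] > 0)),
        S_P_final=int(np.count_nonzero(trajectory.P[-1] > 0)),
        A_total=A_total,
        P_total=P_total,
        F_P=F_P,
        F_A=F_A,
        X_A=X_A,
        X_P=X_P,
        mean_mass_animals=mean_individual_mass(
            A_bar, community.masses_animals, mass_definition),
        mean_mass_plants=mean_individual_mass(
            P_bar, community.masses_plants, mass_definition),
        discarded=discarded,
        seed=seed,
    )
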