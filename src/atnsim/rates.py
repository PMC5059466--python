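"""Pure rate kernels: capture, handling, metabolism, nutrient growth, feeding.

All functions here are deterministic in their inputs. The matrix-valued
:class:`RateCache` precomputes everything that depends only on body masses
and the sampled constants, so that the per-step functional response is a
handful of vectorised array operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Community, ParameterSet

__all__ = [
    "RateCache",
    "NutrientParameters",
    "capture_coefficient",
    "handling_time",
    "metabolic_rate",
    "growth_factor",
    "feeding_rate_matrix",
    "feeding_rates",
    "build_rate_cache",
    "sample_nutrient_parameters",
]


@dataclass(frozen=True)
class NutrientParameters:
    """Two-nutrient chemostat driving the plant compartment.

    ``K`` has one row per plant species and one column per nutrient
    (half-saturation densities, uniform in [0.1, 0.2]); ``v`` is the relative
    nutrient content of plant biomass.
    """

    S: np.ndarray            # supply concentrations, shape (2,)
    K: np.ndarray            # half-saturation, shape (S_P, 2)
    D: float = 0.25
    v: np.ndarray = None     # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "K", np.asarray(self.K, dtype=float))
        v = np.array([1.0, 0.5]) if self.v is None else np.asarray(self.v, float)
        object.__setattr__(self, "v", v)
        if self.D <= 0:
            raise ValueError("turnover rate D must be > 0")
        if np.any(self.S <= 0):
            raise ValueError("supply concentrations must be > 0")


def sample_nutrient_parameters(
    S_P: int,
    rng: np.random.Generator,
    D: float = 0.25,
    mu_S: float = 10.0,
    sigma_S: float = 2.0,
) -> NutrientParameters:
    """Supply concentrations ~ N(mu_S, sigma_S) truncated to be positive;
    half-saturation constants uniform on [0.1, 0.2] per plant and nutrient."""
    S = rng.normal(mu_S, sigma_S, size=2)
    while np.any(S <= 0):
        bad = S <= 0
        S[bad] = rng.normal(mu_S, sigma_S, size=int(bad.sum()))
    K = rng.uniform(0.1, 0.2, size=(S_P, 2))
    return NutrientParameters(S=S, K=K, D=D)


def capture_coefficient(m_i, m_j, is_plant_resource, L_ij, p: ParameterSet):
    """b_ij = b0 * m_i**beta_i * m_j**beta_j * L_ij.

    The resource-mass exponent is the sessile-resource constant when the
    resource is a plant. Zero wherever the link was pruned (L == 0).
    """
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    if np.any(m_i <= 0) or np.any(m_j <= 0):
        raise ValueError("body masses must be positive")
    beta_res = np.where(is_plant_resource, p.beta_res_plant, p.beta_res_animal)
    out = p.b0 * m_i ** p.beta_cons * m_j ** beta_res * np.asarray(L_ij, float)
    return out if np.ndim(out) else float(out)


def handling_time(m_i, m_j, p: ParameterSet):
    """h_ij = h0 * m_i**eta_i * m_j**eta_j (time per unit resource biomass)."""
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    if np.any(m_i <= 0) or np.any(m_j <= 0):
        raise ValueError("body masses must be positive")
    out = p.h0 * m_i ** p.eta_cons * m_j ** p.eta_res
    return out if np.ndim(out) else float(out)


def metabolic_rate(m, x0: float, metab_exp: float = -0.25):
    """Per-unit-biomass metabolic loss rate x(m) = x0 * m**metab_exp."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("body mass must be positive")
    out = x0 * m ** metab_exp
    return out if np.ndim(out) else float(out)


def growth_factor(N, K):
    """Liebig-minimum Monod factor: min over nutrients of N_l / (K_il + N_l).

    ``N`` has shape (2,); ``K`` is (2,) for one plant or (S_P, 2) for all.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("nutrient concentrations must be >= 0")
    K = np.asarray(K, dtype=float)
    G = np.min(N / (K + N), axis=-1)
    return G if np.ndim(G) else float(G)


@dataclass
class RateCache:
    """Mass-derived matrices reused at every right-hand-side evaluation."""

    b: np.ndarray          # capture coefficients, (S_A, S_P + S_A)
    h: np.ndarray          # handling times, same shape
    bh: np.ndarray         # elementwise product b * h
    x_animals: np.ndarray  # per-biomass metabolic rates, (S_A,)
    x_plants: np.ndarray   # (S_P,)
    r: np.ndarray          # per-biomass intrinsic plant growth rates, (S_P,)


def build_rate_cache(community: Community, p: ParameterSet) -> RateCache:
    if community.link_efficiency is None:
        raise ValueError("community has no assembled food web")
    m_a = community.masses_animals
    m_r = community.resource_masses
    is_plant = np.zeros(m_r.size, dtype=bool)
    is_plant[: community.S_P] = True
    b = capture_coefficient(
        m_a[:, None], m_r[None, :], is_plant[None, :],
        community.link_efficiency, p,
    )
    h = handling_time(m_a[:, None], m_r[None, :], p)
    return RateCache(
        b=np.asarray(b),
        h=np.asarray(h),
        bh=np.asarray(b) * np.asarray(h),
        x_animals=np.asarray(metabolic_rate(m_a, p.x_A, p.metab_exp)),
        x_plants=np.asarray(metabolic_rate(community.masses_plants, p.x_P,
                                           p.metab_exp)),
        r=p.r0 * community.masses_plants ** p.growth_exp,
    )


def feeding_rate_matrix(
    A: np.ndarray,
    P: np.ndarray,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
) -> np.ndarray:
    """Per-unit-consumer-biomass feeding rates F_ij for all pairs at once.

    Multi-resource saturating response with Hill exponent ``1 + q`` and
    conspecific interference ``c``::

        F_ij = omega_i * b_ij * R_j^(1+q)
               / ( m_i * [1 + c*A_i + omega_i * sum_k b_ik h_ik R_k^(1+q)] )

    Rows are animal consumers, columns resources (plants then animals).
    """
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(A < 0) or np.any(P < 0):
        raise ValueError("biomass densities must be >= 0")
    R = np.concatenate([P, A])
    Rq = R ** (1.0 + p.q)
    omega = community.omega
    sat = cache.bh @ Rq
    if p.omega_in_denominator:
        sat = omega * sat
    denom = community.masses_animals * (1.0 + p.c * A + sat)
    return (omega[:, None] * cache.b * Rq[None, :]) / denom[:, None]


def feeding_rates(
    consumer_index: int,
    A: np.ndarray,
    P: np.ndarray,
    community: Community,
    cache: RateCache,
    p: ParameterSet,
) -> np.ndarray:
    """Per-resource feeding-rate vector of one consumer (row of the matrix)."""
    return feeding_rate_matrix(A, P, community, cache, p)[consumer_index]
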