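"""Community assembly: body-mass sampling, feeding-efficiency kernel, link pruning.

Species live on a single body-mass niche axis. Plants and animals are drawn
log-uniformly from guild-specific mass ranges; trophic links between an animal
consumer and any resource (plant or animal) are weighted by a hump-shaped
Ricker kernel of the consumer:resource mass ratio, maximal at an optimal
ratio ``R_opt``. Links weaker than a pruning threshold are removed, and each
consumer splits its consumption evenly over its remaining resources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Community",
    "ParameterSet",
    "SamplingConfig",
    "sample_body_masses",
    "feeding_efficiency",
    "build_food_web",
    "sample_parameters",
    "truncated_normal",
]

#: hard cap on redraws for truncated distributions before raising
REDRAW_BUDGET = 10_000


class SamplingError(RuntimeError):
    """Raised when a truncated draw exhausts its redraw budget."""


@dataclass(frozen=True)
class SamplingConfig:
    """Distributions and limits used when sampling one replicate.

    Exponent means/SDs follow the allometric feeding-rate scaling
    literature; they are configurable because the model's qualitative
    behaviour is insensitive to them (only the consumer attack exponent
    ``mu_beta_cons`` has documented leverage on plant-biomass trends).
    """

    log10_mass_limits_plants: tuple[float, float] = (0.0, 6.0)
    log10_mass_limits_animals: tuple[float, float] = (2.0, 12.0)

    # capture-coefficient exponents: consumer and animal-resource body mass
    mu_beta_cons: float = 0.47
    sigma_beta_cons: float = 0.04
    mu_beta_res: float = 0.15
    sigma_beta_res: float = 0.03
    # handling-time exponents
    mu_eta_cons: float = -0.48
    sigma_eta_cons: float = 0.03
    mu_eta_res: float = -0.66
    sigma_eta_res: float = 0.02
    # Hill-exponent modifier q (truncated to [0, 1] inclusive)
    mu_q: float = 0.5
    sigma_q: float = 0.2
    # consumer interference constant
    mu_c: float = 0.8
    sigma_c: float = 0.2

    prune_epsilon: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sigma_beta_cons", "sigma_beta_res", "sigma_eta_cons",
                     "sigma_eta_res", "sigma_q", "sigma_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.prune_epsilon < 0:
            raise ValueError("prune_epsilon must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """All fixed and per-replicate sampled constants of the dynamic model."""

    b0: float = 50.0
    beta_cons: float = 0.47
    beta_res_animal: float = 0.15
    #: sessile resources carry no movement-speed scaling
    beta_res_plant: float = 0.0
    h0: float = 0.4
    eta_cons: float = -0.48
    eta_res: float = -0.66
    q: float = 0.5
    c: float = 0.8
    gamma: float = 2.0
    R_opt: float = 100.0
    e_P: float = 0.45
    e_A: float = 0.85
    x_A: float = 0.314
    x_P: float = 0.138
    metab_exp: float = -0.25
    r0: float = 1.0
    growth_exp: float = -0.25
    #: whether the consumption-splitting weight multiplies the saturation
    #: sum in the functional-response denominator (the source equation is
    #: ambiguous; both readings are supported and this is the default one)
    omega_in_denominator: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if not np.isfinite(self.c):
            raise ValueError("c must be finite")


@dataclass
class Community:
    """One sampled species pool plus its pruned feeding network.

    Resource axis ordering is plants first, then animals: the link matrix
    ``link_efficiency`` has shape ``(S_A, S_P + S_A)`` with column ``j < S_P``
    a plant resource and column ``S_P + k`` the k-th animal.
    """

    masses_plants: np.ndarray
    masses_animals: np.ndarray
    link_efficiency: np.ndarray | None = None
    omega: np.ndarray | None = None
    herbivore_only_mask: np.ndarray | None = None
    prune_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.masses_plants = np.asarray(self.masses_plants, dtype=float)
        self.masses_animals = np.asarray(self.masses_animals, dtype=float)
        if np.any(self.masses_plants <= 0) or np.any(self.masses_animals <= 0):
            raise ValueError("all body masses must be positive")

    @property
    def S_P(self) -> int:
        return self.masses_plants.size

    @property
    def S_A(self) -> int:
        return self.masses_animals.size

    @property
    def resource_masses(self) -> np.ndarray:
        """Masses along the resource axis (plants then animals)."""
        return np.concatenate([self.masses_plants, self.masses_animals])


def sample_body_masses(
    S_P: int,
    S_A: int,
    cfg: SamplingConfig,
    rng: np.random.Generator,
) -> Community:
    """Draw log10 body masses uniformly within guild-specific ranges.

    Returns a :class:`Community` with masses on the linear scale and no
    links assembled yet.
    """
    if S_P < 1 or S_A < 1:
        raise ValueError("S_P and S_A must be >= 1")
    lo_p, hi_p = cfg.log10_mass_limits_plants
    lo_a, hi_a = cfg.log10_mass_limits_animals
    masses_p = 10.0 ** rng.uniform(lo_p, hi_p, size=S_P)
    masses_a = 10.0 ** rng.uniform(lo_a, hi_a, size=S_A)
    return Community(masses_plants=masses_p, masses_animals=masses_a)


def feeding_efficiency(
    m_cons,
    m_res,
    R_opt: float = 100.0,
    gamma: float = 2.0,
):
    """Ricker success curve of the consumer:resource body-mass ratio.

    ``L = [(m_cons / (m_res * R_opt)) * exp(1 - m_cons / (m_res * R_opt))]**gamma``

    Equals 1 exactly at ``m_cons / m_res == R_opt`` and decays to 0 on both
    sides, more slowly toward ratios below the optimum. Accepts scalars or
    broadcastable arrays.
    """
    m_cons = np.asarray(m_cons, dtype=float)
    m_res = np.asarray(m_res, dtype=float)
    if np.any(m_cons <= 0) or np.any(m_res <= 0):
        raise ValueError("body masses must be positive")
    if R_opt <= 0 or gamma <= 0:
        raise ValueError("R_opt and gamma must be positive")
    rel = m_cons / (m_res * R_opt)
    out = (rel * np.exp(1.0 - rel)) ** gamma
    return out if out.ndim else float(out)


def build_food_web(
    community: Community,
    eps: float = 0.01,
    R_opt: float = 100.0,
    gamma: float = 2.0,
    herbivore_only_mask: np.ndarray | None = None,
) -> Community:
    """Assemble the pruned link matrix and the consumption-splitting weights.

    Every (animal, resource) pair gets the kernel value; entries below
    ``eps`` are zeroed, self-links are always removed, and animals flagged in
    ``herbivore_only_mask`` lose all animal-resource links (strict-herbivore
    sensitivity variant). ``omega[i] = 1 / (number of remaining resources)``,
    or 0 for a resource-free animal (it will starve dynamically).
    """
    m_a = community.masses_animals
    m_r = community.resource_masses
    L = feeding_efficiency(m_a[:, None], m_r[None, :], R_opt=R_opt, gamma=gamma)
    L = np.asarray(L, dtype=float)
    L[L < eps] = 0.0
    S_P = community.S_P
    # a species never preys on itself
    np.fill_diagonal(L[:, S_P:], 0.0)
    if herbivore_only_mask is not None:
        mask = np.asarray(herbivore_only_mask, dtype=bool)
        L[mask, S_P:] = 0.0
    n_res = np.count_nonzero(L, axis=1)
    omega = np.where(n_res > 0, 1.0 / np.maximum(n_res, 1), 0.0)
    return replace(
        community,
        link_efficiency=L,
        omega=omega,
        herbivore_only_mask=herbivore_only_mask,
        prune_epsilon=eps,
    )


def truncated_normal(
    rng: np.random.Generator,
    mu: float,
    sigma: float,
    lower: float,
    upper: float,
    inclusive: bool = True,
) -> float:
    """One normal draw rejected until it falls inside [lower, upper].

    ``inclusive=False`` uses strict inequalities (exclusive bounds).
    Raises :class:`SamplingError` after ``REDRAW_BUDGET`` rejections.
    """
    if sigma == 0.0:
        # degenerate distribution: bounds treated inclusively so that
        # sigma=0 returns the mean exactly
        if lower <= mu <= upper:
            return mu
        raise SamplingError("degenerate distribution outside truncation bounds")
    for _ in range(REDRAW_BUDGET):
        x = rng.normal(mu, sigma)
        if (lower <= x <= upper) if inclusive else (lower < x < upper):
            return float(x)
    raise SamplingError(
        f"no draw from N({mu}, {sigma}) within ({lower}, {upper}) "
        f"after {REDRAW_BUDGET} attempts"
    )


def sample_parameters(
    cfg: SamplingConfig,
    rng: np.random.Generator,
    **fixed_overrides,
) -> ParameterSet:
    """Draw the per-replicate constants (one draw per food web, not per species).

    Allometric exponents are resampled until strictly within mean +/- 3 SD;
    ``q`` until within [0, 1] inclusive. Remaining constants come from the
    :class:`ParameterSet` defaults unless overridden by keyword.
    """

    def _pm3(mu: float, sigma: float) -> float:
        return truncated_normal(rng, mu, sigma, mu - 3 * sigma, mu + 3 * sigma,
                                inclusive=False)

    beta_cons = _pm3(cfg.mu_beta_cons, cfg.sigma_beta_cons)
    beta_res = _pm3(cfg.mu_beta_res, cfg.sigma_beta_res)
    eta_cons = _pm3(cfg.mu_eta_cons, cfg.sigma_eta_cons)
    eta_res = _pm3(cfg.mu_eta_res, cfg.sigma_eta_res)
    q = truncated_normal(rng, cfg.mu_q, cfg.sigma_q, 0.0, 1.0, inclusive=True)
    c = float(rng.normal(cfg.mu_c, cfg.sigma_c))
    return ParameterSet(
        beta_cons=beta_cons,
        beta_res_animal=beta_res,
        eta_cons=eta_cons,
        eta_res=eta_res,
        q=q,
        c=c,
        **fixed_overrides,
    )
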