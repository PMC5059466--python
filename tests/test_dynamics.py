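import numpy as np
import pytest
from scipy.optimize import brentq

from atnsim.community import Community, ParameterSet, build_food_web
from atnsim.dynamics import (State, animal_derivatives, nutrient_derivatives,
                             pack_state, plant_derivatives, rhs, rhs_flat)
from atnsim.rates import (NutrientParameters, build_rate_cache, growth_factor,
                          metabolic_rate)
from conftest import make_random_web


def _lonely_animal():
    """One animal with no feeding links at all (starving carnivore)."""
    community = Community(masses_plants=np.array([1.0]),
                          masses_animals=np.array([1e10]))
    p = ParameterSet()
    community = build_food_web(community, eps=0.01)
    assert np.all(community.link_efficiency == 0.0)
    nutrients = NutrientParameters(S=np.array([10.0, 10.0]),
                                   K=np.array([[0.15, 0.15]]))
    return community, p, build_rate_cache(community, p), nutrients


class TestAnimalDerivatives:
    def test_zero_biomass_absorbing(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        state = State(A=np.zeros(community.S_A),
                      P=rng.uniform(0, 5, community.S_P),
                      N=np.array([1.0, 1.0]))
        dA = animal_derivatives(state, community, cache, p)
        np.testing.assert_array_equal(dA, np.zeros(community.S_A))

    def test_starving_animal_pure_decay(self):
        community, p, cache, nutrients = _lonely_animal()
        A0 = 3.7
        state = State(A=np.array([A0]), P=np.array([0.0]),
                      N=np.array([1.0, 1.0]))
        dA = animal_derivatives(state, community, cache, p)
        x = metabolic_rate(1e10, p.x_A)
        assert dA[0] == pytest.approx(-x * A0, rel=1e-12)

    def test_saturated_growth_limit(self):
        community = Community(masses_plants=np.array([1.0]),
                              masses_animals=np.array([100.0]))
        p = ParameterSet(q=0.0, c=0.0)
        community = build_food_web(community, eps=0.01)
        cache = build_rate_cache(community, p)
        m_i, h = 100.0, cache.h[0, 0]
        state = State(A=np.array([1e-9]), P=np.array([1e14]),
                      N=np.array([1.0, 1.0]))
        dA = animal_derivatives(state, community, cache, p)
        per_biomass = dA[0] / 1e-9
        expected = p.e_P / (m_i * h) - metabolic_rate(m_i, p.x_A)
        assert per_biomass == pytest.approx(expected, rel=1e-4)


class TestPlantDerivatives:
    def test_zero_biomass_absorbing(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        state = State(A=rng.uniform(0, 5, community.S_A),
                      P=np.zeros(community.S_P),
                      N=np.array([1.0, 1.0]))
        dP = plant_derivatives(state, community, cache, p, nutrients)
        np.testing.assert_array_equal(dP, np.zeros(community.S_P))

    def test_no_animals_scalar_oracle(self, rng):
        community, p, nutrients = make_random_web(rng, S_P=3, S_A=2)
        cache = build_rate_cache(community, p)
        P = rng.uniform(1, 5, 3)
        state = State(A=np.zeros(2), P=P, N=nutrients.S.copy())
        dP = plant_derivatives(state, community, cache, p, nutrients)
        for i in range(3):
            m = community.masses_plants[i]
            r_i = p.r0 * m ** p.growth_exp
            G_i = min(nutrients.S[l] / (nutrients.K[i, l] + nutrients.S[l])
                      for l in range(2))
            expected = (r_i * G_i - 0.138 * m ** -0.25) * P[i]
            assert dP[i] == pytest.approx(expected, rel=1e-12)

    def test_grazing_is_gross_flow(self, rng):
        # plant losses carry no assimilation efficiency
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        from atnsim.rates import feeding_rate_matrix
        A = rng.uniform(0.5, 5, community.S_A)
        P = rng.uniform(0.5, 5, community.S_P)
        N = np.array([3.0, 3.0])
        state = State(A=A, P=P, N=N)
        F = feeding_rate_matrix(A, P, community, cache, p)
        G = growth_factor(N, nutrients.K)
        dP = plant_derivatives(state, community, cache, p, nutrients)
        for i in range(community.S_P):
            grazing = sum(F[k, i] * A[k] for k in range(community.S_A))
            expected = (cache.r[i] * G[i] * P[i] - grazing
                        - cache.x_plants[i] * P[i])
            assert dP[i] == pytest.approx(expected, rel=1e-10)


class TestNutrientDerivatives:
    def test_no_plants_linear_relaxation(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        N = np.array([2.0, 11.0])
        state = State(A=rng.uniform(0, 5, community.S_A),
                      P=np.zeros(community.S_P), N=N)
        dN = nutrient_derivatives(state, community, cache, p, nutrients)
        np.testing.assert_allclose(dN, nutrients.D * (nutrients.S - N),
                                   rtol=1e-12)

    def test_supply_equilibrium(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        state = State(A=np.zeros(community.S_A),
                      P=np.zeros(community.S_P), N=nutrients.S.copy())
        dN = nutrient_derivatives(state, community, cache, p, nutrients)
        np.testing.assert_allclose(dN, [0.0, 0.0], atol=1e-14)

    def test_nutrient_two_drains_at_half_rate(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        # symmetric nutrient state so uptake is identical for both nutrients
        N = np.array([4.0, 4.0])
        nut = NutrientParameters(S=np.array([4.0, 4.0]),
                                 K=np.full((community.S_P, 2), 0.15),
                                 D=nutrients.D)
        state = State(A=np.zeros(community.S_A),
                      P=np.full(community.S_P, 2.0), N=N)
        dN = nutrient_derivatives(state, community, cache, p, nut)
        # D(S-N)=0, so dN is pure uptake drain: v = (1, 0.5)
        assert dN[1] == pytest.approx(0.5 * dN[0], rel=1e-12)
        assert dN[0] < 0


class TestRhs:
    def test_all_zero_biomass(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        N = np.array([1.0, 6.0])
        state = State(A=np.zeros(community.S_A), P=np.zeros(community.S_P), N=N)
        d = rhs(state, community, cache, p, nutrients)
        np.testing.assert_array_equal(d.dA, 0.0)
        np.testing.assert_array_equal(d.dP, 0.0)
        np.testing.assert_allclose(d.dN, nutrients.D * (nutrients.S - N))

    def test_conservation_of_assimilation_flows(self, rng):
        """Animal gains equal e times the corresponding prey-side losses."""
        from atnsim.rates import feeding_rate_matrix
        community, p, nutrients = make_random_web(rng, S_P=6, S_A=10)
        cache = build_rate_cache(community, p)
        S_P = community.S_P
        for _ in range(1000):
            A = rng.uniform(0, 10, community.S_A)
            P = rng.uniform(0, 10, community.S_P)
            F = feeding_rate_matrix(A, P, community, cache, p)
            flow = F * A[:, None]
            herbivory_gain = p.e_P * flow[:, :S_P].sum()
            plant_loss = flow[:, :S_P].sum()
            assert herbivory_gain == pytest.approx(p.e_P * plant_loss,
                                                   rel=1e-10)
            carnivory_gain = p.e_A * flow[:, S_P:].sum()
            animal_loss = flow[:, S_P:].sum()
            assert carnivory_gain == pytest.approx(p.e_A * animal_loss,
                                                   rel=1e-10)
            # and the rhs blocks are consistent with these flows
            state = State(A=A, P=P, N=np.array([2.0, 2.0]))
            d = rhs(state, community, cache, p, nutrients)
            gain_terms = (p.e_P * flow[:, :S_P].sum(axis=1)
                          + p.e_A * flow[:, S_P:].sum(axis=1))
            pred_loss = flow[:, S_P:].sum(axis=0)
            metab = cache.x_animals * A
            np.testing.assert_allclose(
                d.dA, gain_terms - pred_loss - metab, rtol=1e-9, atol=1e-12)

    def test_rhs_flat_matches_structured(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        state = State(A=rng.uniform(0, 5, community.S_A),
                      P=rng.uniform(0, 5, community.S_P),
                      N=np.array([1.5, 2.5]))
        d = rhs(state, community, cache, p, nutrients)
        flat = rhs_flat(0.0, pack_state(state), community, cache, p, nutrients)
        np.testing.assert_allclose(
            flat, np.concatenate([d.dA, d.dP, d.dN]), rtol=1e-13)

    def test_single_plant_equilibrium_root_vs_integration(self):
        from atnsim.simulator import SimulationSettings, integrate
        community = Community(masses_plants=np.array([10.0]),
                              masses_animals=np.array([1e10]))
        p = ParameterSet()
        community = build_food_web(community, eps=0.01)  # animal linkless
        cache = build_rate_cache(community, p)
        nutrients = NutrientParameters(S=np.array([10.0, 10.0]),
                                       K=np.array([[0.15, 0.12]]))
        settings = SimulationSettings(t_end=2000.0, eval_window=100.0,
                                      rel_tol=1e-10, abs_tol=1e-10)
        state0 = State(A=np.array([0.0]), P=np.array([1.0]),
                       N=np.array([8.0, 8.0]))
        traj = integrate(community, cache, p, nutrients, settings, state0)
        P_end = traj.P[-1, 0]
        N_end = traj.N[-1]

        # independent equilibrium: dP = 0 gives r G(N) = x_P; with
        # dN = 0, N_l = S_l - v_l r G P / D. Solve scalar root in P.
        r = cache.r[0]
        x = cache.x_plants[0]

        def g(Pstar):
            N = nutrients.S - nutrients.v * r_g_up(Pstar)
            G = growth_factor(np.clip(N, 1e-12, None), nutrients.K[0])
            return r * G - x

        def r_g_up(Pstar):
            # uptake at equilibrium equals metabolic loss x * P
            return x * Pstar / nutrients.D

        Pstar = brentq(g, 1e-6, 1e6, xtol=1e-12, rtol=1e-12)
        assert P_end == pytest.approx(Pstar, rel=1e-5)
        N_expected = nutrients.S - nutrients.v * x * Pstar / nutrients.D
        np.testing.assert_allclose(N_end, N_expected, rtol=1e-5)

    def test_nan_input_rejected(self, rng):
        community, p, nutrients = make_random_web(rng)
        cache = build_rate_cache(community, p)
        with pytest.raises(ValueError):
            state = State(A=np.full(community.S_A, np.nan),
                          P=np.zeros(community.S_P),
                          N=np.array([1.0, 1.0]))
            rhs(state, community, cache, p, nutrients)
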