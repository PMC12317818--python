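import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

import nutrideb as nd

ADC = {"protein": 0.9, "fat": 0.9, "carb": 0.7}


class TestStomachCapacity:
    def test_no_water_limit(self, diet, params):
        dry = dataclasses.replace(params.digestion, y_HXd=1e-12)
        cap = nd.max_stomach_capacity(diet, dry)
        expected = params.digestion.delta_g * diet.d_Xd / diet.w_X
        assert cap == pytest.approx(expected, rel=1e-9)

    def test_inverse_in_molar_weight(self, diet, params):
        cap = nd.max_stomach_capacity(diet, params.digestion)
        heavier = dataclasses.replace(diet, w_X=2 * diet.w_X)
        assert nd.max_stomach_capacity(heavier, params.digestion) == \
            pytest.approx(cap / 2, rel=1e-12)

    def test_capacity_fills_stomach_volume_exactly(self, diet, params):
        # substitute [M_gm]*V back: dry volume + moisturising water = V_g
        V = 80.0
        M_gm = nd.max_stomach_capacity(diet, params.digestion) * V
        dry_mass = M_gm * diet.w_X
        volume = (params.digestion.y_HXd * dry_mass / 1.0
                  + dry_mass / diet.d_Xd)
        assert volume == pytest.approx(params.digestion.delta_g * V, rel=1e-9)


class TestHalfSaturation:
    def test_single_substrate_diets_have_infinite_MKX(self, params):
        for fracs in [(1.0, 0.0, 0.0), (0.0, 0.6, 0.4)]:
            d = nd.diet_from_proximate(
                dict(zip(("protein", "fat", "carb"), fracs), ash=0.0), ADC)
            y = nd.coupling_yields(d, params.reserve)
            assert math.isinf(nd.half_saturation(d, y, params.digestion))

    def test_symmetric_su_closed_form(self, params, diet):
        # q_P = q_nP = q and a_P = 1/2 collapse to M_KX = 3 q JEAm/JXgm
        q = 0.9
        y = dataclasses.replace(
            nd.coupling_yields(diet, params.reserve), q_P=q, q_nP=q)
        half = dataclasses.replace(diet, a_P=0.5)
        expected = 3 * q * params.digestion.J_EAm_d / params.digestion.J_Xg_m
        assert nd.half_saturation(half, y, params.digestion) == \
            pytest.approx(expected, rel=1e-12)

    def test_unique_interior_minimum_in_aP(self, params, diet, yields):
        def mkx(a):
            d = dataclasses.replace(diet, a_P=a)
            return nd.half_saturation(d, yields, params.digestion)

        grid = np.linspace(0.01, 0.99, 400)
        vals = np.array([mkx(a) for a in grid])
        d = np.diff(vals)
        sign_changes = np.sum(np.diff(np.sign(d)) != 0)
        assert sign_changes == 1
        # calculus oracle: scalar minimiser lands on the same interior point
        res = minimize_scalar(mkx, bounds=(0.01, 0.99), method="bounded")
        assert abs(grid[np.argmin(vals)] - res.x) < 0.01


class TestFunctionalResponse:
    @pytest.mark.parametrize("M_X,M_KX,expected", [
        (0.0, 0.02, 0.0),
        (0.02, 0.02, 0.5),
        (1.0, math.inf, 0.0),
    ])
    def test_reference_points(self, M_X, M_KX, expected):
        assert nd.functional_response(M_X, M_KX) == pytest.approx(expected)

    def test_bounded_below_one(self):
        assert 0 <= nd.functional_response(1e6, 1.0) < 1


class TestAssimilationFlux:
    def test_fasting_gives_zero(self, params):
        J, pA = nd.assimilation_flux(0.0, 5.0, params.digestion,
                                     params.core.mu_E)
        assert J == 0.0 and pA == 0.0

    def test_surface_area_scaling(self, params):
        J1, _ = nd.assimilation_flux(0.5, 2.0, params.digestion,
                                     params.core.mu_E)
        J2, _ = nd.assimilation_flux(0.5, 4.0, params.digestion,
                                     params.core.mu_E)
        assert J2 == pytest.approx(4 * J1, rel=1e-12)

    def test_saturation_limit(self, params):
        L = 3.0
        J, pA = nd.assimilation_flux(1.0, L, params.digestion,
                                     params.core.mu_E)
        assert J == pytest.approx(params.digestion.J_EAm_d * L * L)
        assert pA == pytest.approx(params.core.mu_E * J)


class TestSubstrateAndFaecesFluxes:
    def test_zero_assimilation_zero_fluxes(self, yields):
        assert nd.substrate_and_faeces_fluxes(0.0, yields) == (0.0, 0.0, 0.0)

    def test_fully_digestible_no_faeces(self, params):
        d = nd.diet_from_proximate(
            {"protein": 0.5, "fat": 0.3, "carb": 0.2, "ash": 0.0},
            {"protein": 1.0, "fat": 1.0, "carb": 1.0})
        y = nd.coupling_yields(d, params.reserve)
        _, _, J_P = nd.substrate_and_faeces_fluxes(0.01, y)
        assert J_P == pytest.approx(0.0, abs=1e-14)

    def test_outflow_matches_stomach_ode_coefficient(self, params, diet,
                                                     yields):
        # total C-mol/d leaving the stomach must equal -dM_X/dt
        M_KX = nd.half_saturation(diet, yields, params.digestion)
        L, M_X = 4.0, 0.05
        f = nd.functional_response(M_X, M_KX)
        J_EA, _ = nd.assimilation_flux(f, L, params.digestion,
                                       params.core.mu_E)
        outflow = sum(nd.substrate_and_faeces_fluxes(J_EA, yields))
        dMX = nd.stomach_ode(M_X, L, M_KX, yields, params.digestion)
        assert dMX == pytest.approx(-outflow, rel=1e-12)


class TestMealIntake:
    def test_full_stomach_eats_nothing(self, params, diet):
        V, W = 80.0, 150.0
        cap = nd.max_stomach_capacity(diet, params.digestion) * V
        res = nd.meal_intake(cap, V, W, 0.012, diet, params.digestion)
        assert res.eaten == 0.0
        assert res.uneaten == pytest.approx(res.offered)

    def test_small_ration_fully_eaten(self, params, diet):
        res = nd.meal_intake(0.0, 80.0, 150.0, 1e-4, diet, params.digestion)
        assert res.eaten == pytest.approx(res.offered, rel=1e-12)
        assert res.uneaten == 0.0

    def test_eq5_arithmetic_for_150g_fish(self, params, diet):
        # 1.2 % of body weight in one meal, empty and capacious stomach
        res = nd.meal_intake(0.0, 500.0, 150.0, 0.012, diet,
                             params.digestion)
        expected = 0.012 * 150.0 * diet.d_Xd / diet.d_Xw / diet.w_X
        assert res.eaten == pytest.approx(expected, rel=1e-12)

    def test_numerical_overshoot_clipped(self, params, diet):
        V = 10.0
        cap = nd.max_stomach_capacity(diet, params.digestion) * V
        res = nd.meal_intake(cap * (1 + 1e-12), V, 20.0, 0.01, diet,
                             params.digestion)
        assert res.eaten == 0.0


class TestStomachODE:
    def test_empty_stomach_stays_empty(self, params, diet, yields):
        M_KX = nd.half_saturation(diet, yields, params.digestion)
        assert nd.stomach_ode(0.0, 4.0, M_KX, yields, params.digestion) == 0.0

    def test_matches_separable_ode_implicit_solution(self, params, diet,
                                                     yields):
        """For constant L the trajectory satisfies
        M(t) - M(0) + M_KX ln(M(t)/M(0)) = -k t to 1e-6 relative."""
        M_KX = nd.half_saturation(diet, yields, params.digestion)
        L, M0 = 3.0, 0.05
        k = (yields.total_food_per_reserve * params.digestion.J_EAm_d * L * L)
        t_eval = np.linspace(0.1, 4.0, 20)
        sol = solve_ivp(
            lambda t, y: [nd.stomach_ode(y[0], L, M_KX, yields,
                                         params.digestion)],
            (0, 4.0), [M0], t_eval=t_eval, rtol=1e-10, atol=1e-16,
            method="LSODA")
        M = sol.y[0]
        implicit = M - M0 + M_KX * np.log(M / M0)
        assert np.max(np.abs(implicit + k * t_eval) / (k * t_eval)) < 1e-6

    def test_warmer_fish_empty_faster(self, params, diet, yields):
        M_KX = nd.half_saturation(diet, yields, params.digestion)
        rates = [nd.stomach_ode(0.05, 3.0, M_KX, yields, params.digestion,
                                temp_factor=c) for c in (0.5, 1.0, 1.5)]
        assert rates[0] > rates[1] > rates[2]   # more negative when warm
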