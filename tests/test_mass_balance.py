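import dataclasses

import numpy as np
import pytest

import nutrideb as nd
from nutrideb.mass_balance import (_N_MINERAL, _element_matrix,
                                   organic_flux_matrix,
                                   structure_moles_per_joule)

ADC = {"protein": 0.9, "fat": 0.9, "carb": 0.7}


@pytest.fixture(scope="module")
def eta(params, diet, yields):
    return nd.eta_matrix(diet, yields, params.reserve, params.structure,
                         params.core)


class TestEtaMatrix:
    def test_nitrogen_free_world_excretes_no_nitrogen(self, params):
        # hypothetical: N-free reserve/structure and a protein-free feed
        lib = nd.build_compound_library({
            "reserve": {"n_N": 0.0}, "structure": {"n_N": 0.0}})
        d = nd.diet_from_proximate(
            {"protein": 0.0, "fat": 0.5, "carb": 0.5, "ash": 0.0}, ADC,
            library=lib)
        y = nd.coupling_yields(d, lib["reserve"])
        core = dataclasses.replace(params.core)
        e = nd.eta_matrix(d, y, lib["reserve"], lib["structure"], core)
        assert e.eta_NA == pytest.approx(0.0, abs=1e-15)
        assert e.eta_ND == pytest.approx(0.0, abs=1e-15)
        assert e.eta_NG == pytest.approx(0.0, abs=1e-15)
        assert nd.mineral_fluxes(100.0, 100.0, 100.0, e)[2] == 0.0

    def test_assimilation_ammonia_vanishes_by_closure(self, eta):
        # the nitrogen-exact yields route all assimilation N to reserve+faeces
        assert abs(eta.eta_NA) < 1e-15

    def test_diet_switch_changes_assimilation_not_growth_chemistry(
            self, params, diet, yields, eta):
        other = nd.diet_from_proximate(
            {"protein": 0.30, "fat": 0.38, "carb": 0.19, "ash": 0.13}, ADC,
            library=params.library)
        y2 = nd.coupling_yields(other, params.reserve,
                                params.digestion.kappa_A)
        e2 = nd.eta_matrix(other, y2, params.reserve, params.structure,
                          params.core)
        # assimilation oxygen demand tracks the substrate chemistry ...
        assert e2.eta_OA != pytest.approx(eta.eta_OA, rel=1e-6)
        # ... while growth chemistry (reserve -> structure) is unchanged
        assert e2.eta_OG == pytest.approx(eta.eta_OG, rel=1e-12)
        assert e2.eta_CG == pytest.approx(eta.eta_CG, rel=1e-12)
        assert e2.eta_NG == pytest.approx(eta.eta_NG, rel=1e-12)

    def test_elemental_closure_for_arbitrary_powers(self, params, diet,
                                                    yields, eta):
        """Brute-force audit: organic + mineral elemental fluxes sum to zero
        for every element at any combination of the three powers."""
        n_org = _element_matrix([diet.comp_XP, diet.comp_XnP, params.reserve,
                                 params.structure, yields.comp_P])
        j_org = organic_flux_matrix(yields, params.structure, params.core)
        rng = np.random.default_rng(1)
        scale = np.max(np.abs(n_org @ j_org))
        for _ in range(10):
            powers = rng.uniform(0.0, 5e4, size=3)
            residual = (n_org @ (j_org @ powers)
                        + _N_MINERAL @ (eta.as_array() @ powers))
            assert np.max(np.abs(residual)) < 1e-9 * scale * np.max(powers)


class TestMineralFluxes:
    def test_linear_in_powers(self, eta):
        one = nd.mineral_fluxes(1e3, 2e3, 5e2, eta)
        two = nd.mineral_fluxes(2e3, 4e3, 1e3, eta)
        assert two == pytest.approx(tuple(2 * x for x in one), rel=1e-12)

    def test_fasted_fish_still_respires(self, params, eta):
        J_O, J_C, J_N = nd.mineral_fluxes(0.0, 5e3, 1e3, eta)
        assert J_O > 0 and J_C > 0 and J_N > 0

    def test_feeding_raises_oxygen_demand(self, params, diet, eta):
        # same state, fed vs fasted: the assimilation overhead costs oxygen
        state = nd.initial_state_from_weight(150.0, 0.8, params.core)
        fed = nd.deb_fluxes(state, 0.8, 288.15, params.core)
        fasted = nd.deb_fluxes(state, 0.0, 288.15, params.core)
        J_O_fed, *_ = nd.mineral_fluxes(fed.p_A, fed.p_D, fed.p_G, eta)
        J_O_fast, *_ = nd.mineral_fluxes(fasted.p_A, fasted.p_D,
                                         fasted.p_G, eta)
        assert J_O_fed > J_O_fast


class TestFaecalNitrogen:
    def test_protein_free_diet_sheds_no_faecal_n(self, params):
        d = nd.diet_from_proximate(
            {"protein": 0.0, "fat": 0.5, "carb": 0.5, "ash": 0.0}, ADC,
            library=params.library)
        y = nd.coupling_yields(d, params.reserve)
        # a_P = 0 nullifies assimilation, so p_A = 0 downstream
        assert nd.faecal_nitrogen(0.0, y, params.core) == 0.0

    def test_proportional_to_assimilation(self, params, yields):
        j1 = nd.faecal_nitrogen(1e3, yields, params.core)
        assert nd.faecal_nitrogen(2e3, yields, params.core) == \
            pytest.approx(2 * j1, rel=1e-12)

    def test_protein_for_carbohydrate_swap_raises_nitrogen_waste(
            self, params, diet):
        """Replacing protein with carbohydrate at equal ration lowers total
        nitrogen output (faecal N + TAN): the carbohydrate-diluted feed
        digests and assimilates less, and every flux of the nitrogen
        pathway scales with reserve formation."""
        diluted = nd.diet_from_proximate(
            {"protein": 0.30, "fat": 0.22, "carb": 0.35, "ash": 0.13}, ADC,
            library=params.library)

        def total_n_over_run(d):
            scenario = nd.Scenario(
                duration=10.0, initial_weight=150.0, temperature=15.0,
                schedule=nd.FeedingSchedule.daily(10.0, 0.012, 1,
                                                  diet_id="d"),
                diets={"d": d})
            out = nd.simulate(scenario, params)
            h = out.hourly
            return (h["TAN_gN_per_d"] + h["faecalN_gN_per_d"]).mean()

        assert total_n_over_run(diet) > total_n_over_run(diluted)


class TestSolidWaste:
    def test_ash_free_diet_is_organic_only(self, params, yields):
        d = nd.diet_from_proximate(
            {"protein": 0.5, "fat": 0.3, "carb": 0.2, "ash": 0.0}, ADC,
            library=params.library)
        y = nd.coupling_yields(d, params.reserve)
        J_P = 0.01
        assert nd.solid_waste(J_P, d, y, 0.05) == pytest.approx(
            J_P * y.comp_P.w, rel=1e-12)

    def test_ash_rides_along_with_digestion(self, diet, yields):
        with_ash = nd.solid_waste(0.01, diet, yields, 0.05)
        assert with_ash == pytest.approx(
            0.01 * yields.comp_P.w + 0.05 * diet.ash_per_cmol, rel=1e-12)

    def test_uneaten_feed_never_negative(self, run_12pct):
        assert (run_12pct.meals["uneaten_g"] >= 0).all()
        assert np.allclose(run_12pct.meals["offered_g"],
                           run_12pct.meals["eaten_g"]
                           + run_12pct.meals["uneaten_g"])


class TestWholeRunAudit:
    def test_carbon_budget_over_closed_simulation(self, params, diet,
                                                  run_12pct):
        """Feed eaten = stomach residue + body reserve/structure gain +
        faeces + respired CO2, all in C-mol, to 1e-6 over 30 days."""
        cum = run_12pct.cumulative
        mu = params.core.mu_E
        ctx = cum["final_diet_context"]
        eaten_C = cum["feed_eaten_g"] / diet.w_X
        J_EA = cum["p_A_J"] / mu
        # stomach: eaten = residue + outflow
        outflow = ctx.yields.total_food_per_reserve * J_EA
        assert eaten_C == pytest.approx(cum["final_M_X_mol"] + outflow,
                                        rel=1e-6)
        # body + faeces + CO2 account for the outflow
        state0 = nd.initial_state_from_weight(150.0, 0.8, params.core)
        final = cum["final_state"]
        dM_E = (final.E + final.E_R - state0.E) / mu
        y_VG = structure_moles_per_joule(params.core, params.structure)
        dM_V = params.core.d_Vd / params.structure.w * (final.V - state0.V)
        faeces_C = ctx.yields.y_PE * J_EA
        co2_C = (ctx.eta.eta_CA * cum["p_A_J"]
                 + ctx.eta.eta_CD * cum["p_D_J"]
                 + ctx.eta.eta_CG * cum["p_G_J"])
        assert outflow == pytest.approx(dM_E + dM_V + faeces_C + co2_C,
                                        rel=1e-6)
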