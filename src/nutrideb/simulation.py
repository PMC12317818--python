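"""Event-driven simulation of the coupled stomach + DEB state.

Between meals the five coupled states (structure V, reserve E, maturity E_H,
reproduction buffer E_R, stomach content M_X) follow smooth ODE dynamics and
are integrated with an adaptive stiff-safe integrator; each meal is a
stop-jump-restart event that instantaneously tops up the stomach subject to
its moisture-corrected capacity.  Outputs are hourly time series of weight,
functional response, stomach content and all waste fluxes; daily output is
the aggregate of the hourly series (mean rates, summed masses).

The module also produces the diet-composition response surfaces: satiation
food intake and realized assimilation over grids of protein fraction and of
the fat share of the non-protein component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import deb_core, digestion, mass_balance
from .deb_core import FishState
from .feed_chemistry import CouplingYields, DietSpec, coupling_yields, diet_from_proximate
from .params import ModelParams

__all__ = [
    "Meal",
    "FeedingSchedule",
    "TemperatureSeries",
    "Scenario",
    "SimulationOutput",
    "DigestContext",
    "simulate",
    "diet_response_surface",
    "intake_vs_energy",
    "satiation_intake",
    "aggregate_daily",
]

KELVIN = 273.15

#: rate / state columns averaged and mass columns summed when aggregating
RATE_COLUMNS = [
    "W_g", "f_X", "M_X_mol", "JO_gO2_per_d", "JC_gCO2_per_d",
    "TAN_gN_per_d", "faecalN_gN_per_d", "faeces_dry_g_per_d",
    "uneaten_g_per_d", "V_cm3", "E_J", "E_H_J", "E_R_J",
    "p_A_J_per_d", "p_D_J_per_d", "p_G_J_per_d",
]
#: per-fish state columns that must not be scaled to population totals
PER_FISH_COLUMNS = ("time", "W_g", "f_X", "V_cm3", "E_J", "E_H_J", "E_R_J")
MASS_COLUMNS = ["eaten_g", "uneaten_g"]


@dataclass(frozen=True)
class Meal:
    time: float          # d since simulation start
    ration: float        # fraction of current wet body weight
    diet_id: str = "default"


@dataclass(frozen=True)
class FeedingSchedule:
    """Discrete meals; an empty schedule is fasting."""

    meals: tuple[Meal, ...]

    def __post_init__(self) -> None:
        times = [m.time for m in self.meals]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("meal times must be strictly increasing")
        if any(m.ration < 0 for m in self.meals):
            raise ValueError("meal rations must be non-negative")

    @classmethod
    def daily(cls, duration: float, daily_fraction: float,
              meals_per_day: int = 1, diet_id: str = "default",
              first_meal_hour: float = 8.0) -> "FeedingSchedule":
        """Equal meals every day, the daily ration split evenly.

        Meals are placed within the waking day starting at
        ``first_meal_hour`` and spaced 4 h apart (1 meal: 08:00; 3 meals:
        08:00, 12:00, 16:00), mirroring common hatchery practice.
        """
        if meals_per_day < 1:
            raise ValueError("meals_per_day must be >= 1")
        per_meal = daily_fraction / meals_per_day
        meals = []
        for day in range(int(np.ceil(duration))):
            for k in range(meals_per_day):
                t = day + (first_meal_hour + 4.0 * k) / 24.0
                if t < duration:
                    meals.append(Meal(time=t, ration=per_meal, diet_id=diet_id))
        return cls(meals=tuple(meals))


class TemperatureSeries:
    """Piecewise-constant temperature (degC) over time (d)."""

    def __init__(self, temperature: float | list[tuple[float, float]]):
        if np.isscalar(temperature):
            self._times = np.array([0.0])
            self._values = np.array([float(temperature)])
        else:
            pts = sorted(temperature)
            self._times = np.array([p[0] for p in pts])
            self._values = np.array([p[1] for p in pts])
            if len(self._times) == 0:
                raise ValueError("temperature series cannot be empty")

    def at(self, t: float) -> float:
        """Temperature in degC at time t (constant before the first point)."""
        idx = np.searchsorted(self._times, t, side="right") - 1
        return float(self._values[max(idx, 0)])

    def kelvin_at(self, t: float) -> float:
        return self.at(t) + KELVIN

    @property
    def breakpoints(self) -> np.ndarray:
        return self._times


@dataclass
class Scenario:
    """Rearing conditions of one simulation run."""

    duration: float                       # d
    initial_weight: float                 # g
    temperature: float | list             # degC, scalar or [(d, degC), ...]
    schedule: FeedingSchedule
    diets: dict[str, DietSpec]
    n_fish: int = 1
    output_resolution: str = "hourly"     # 'hourly' | 'daily'
    f_initial: float = 0.8                # assumed reserve density at start
    seed: int | None = None               # fixtures only

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.output_resolution not in ("hourly", "daily"):
            raise ValueError("output_resolution must be 'hourly' or 'daily'")
        for meal in self.schedule.meals:
            if meal.diet_id not in self.diets:
                raise KeyError(
                    f"meal at t={meal.time} references unknown diet "
                    f"'{meal.diet_id}'")


@dataclass(frozen=True)
class DigestContext:
    """Per-diet quantities the integrator needs, computed once."""

    diet: DietSpec
    yields: CouplingYields
    M_KX: float                     # mol (inf for single-substrate diets)
    capacity_density: float         # [M_gm], mol/cm^3
    eta: mass_balance.EtaMatrix

    @classmethod
    def build(cls, diet: DietSpec, params: ModelParams) -> "DigestContext":
        yields = coupling_yields(diet, params.reserve,
                                 params.digestion.kappa_A)
        return cls(
            diet=diet,
            yields=yields,
            M_KX=digestion.half_saturation(diet, yields, params.digestion),
            capacity_density=digestion.max_stomach_capacity(
                diet, params.digestion),
            eta=mass_balance.eta_matrix(diet, yields, params.reserve,
                                        params.structure, params.core),
        )


@dataclass
class SimulationOutput:
    """Per-fish time series plus meal log and run diagnostics."""

    hourly: pd.DataFrame
    daily: pd.DataFrame
    meals: pd.DataFrame
    cumulative: dict
    n_fish: int
    diagnostics: list = field(default_factory=list)
    terminated_early: bool = False

    def population(self, resolution: str = "hourly") -> pd.DataFrame:
        """Time series scaled to the whole group of ``n_fish`` fish."""
        df = (self.hourly if resolution == "hourly" else self.daily).copy()
        for col in df.columns:
            if col in PER_FISH_COLUMNS:
                continue
            df[col] = df[col] * self.n_fish
        return df


def _blend_diets(resident: DietSpec, incoming: DietSpec,
                 m_res: float, m_in: float, params: ModelParams) -> DietSpec:
    """Mass-weighted re-pooling of stomach content on a diet switch."""
    tot_res = m_res / max(1.0 - resident.frac_ash, 1e-12)
    tot_in = m_in / max(1.0 - incoming.frac_ash, 1e-12)
    w = tot_res + tot_in
    fracs = {
        key: (tot_res * getattr(resident, f"frac_{key}")
              + tot_in * getattr(incoming, f"frac_{key}")) / w
        for key in ("protein", "fat", "carb", "ash")
    }
    adc = {}
    for key in ("protein", "fat", "carb"):
        m1 = tot_res * getattr(resident, f"frac_{key}")
        m2 = tot_in * getattr(incoming, f"frac_{key}")
        if m1 + m2 > 0:
            adc[key] = (m1 * getattr(resident, f"adc_{key}")
                        + m2 * getattr(incoming, f"adc_{key}")) / (m1 + m2)
        else:
            adc[key] = getattr(incoming, f"adc_{key}")
    return diet_from_proximate(
        fracs, adc,
        densities={"dry": incoming.d_Xd, "wet": incoming.d_Xw},
        moisture=incoming.moisture, name="pooled")


def _instantaneous_rates(y: np.ndarray, T_K: float, ctx: DigestContext,
                         params: ModelParams) -> dict:
    """All reported quantities at one instant, per fish."""
    V, E, E_H, E_R, M_X = y[:5]
    state = FishState(V=V, E=max(E, 0.0), E_H=E_H, E_R=max(E_R, 0.0))
    f_X = digestion.functional_response(max(M_X, 0.0), ctx.M_KX)
    fluxes = deb_core.deb_fluxes(state, f_X, T_K, params.core)
    J_O, J_C, J_N = mass_balance.mineral_fluxes(
        fluxes.p_A, fluxes.p_D, fluxes.p_G, ctx.eta)
    J_EA = fluxes.p_A / params.core.mu_E
    J_P = ctx.yields.y_PE * J_EA
    outflow = ctx.yields.total_food_per_reserve * J_EA
    return {
        "W_g": deb_core.wet_weight(state, params.core),
        "f_X": f_X,
        "M_X_mol": max(M_X, 0.0),
        "JO_gO2_per_d": J_O * mass_balance.GRAMS_PER_MOL["O2"],
        "JC_gCO2_per_d": J_C * mass_balance.GRAMS_PER_MOL["CO2"],
        "TAN_gN_per_d": J_N * mass_balance.GRAMS_PER_MOL["N"],
        "faecalN_gN_per_d": mass_balance.faecal_nitrogen(
            fluxes.p_A, ctx.yields, params.core),
        "faeces_dry_g_per_d": mass_balance.solid_waste(
            J_P, ctx.diet, ctx.yields, outflow),
        "V_cm3": V, "E_J": max(E, 0.0), "E_H_J": E_H,
        "E_R_J": max(E_R, 0.0),
        "p_A_J_per_d": fluxes.p_A, "p_D_J_per_d": fluxes.p_D,
        "p_G_J_per_d": fluxes.p_G,
    }


def simulate(scenario: Scenario, params: ModelParams) -> SimulationOutput:
    """Run one scenario; deterministic given inputs.

    Returns hourly and daily per-fish time series (population totals are the
    per-fish values times ``n_fish``), the meal log with offered / eaten /
    uneaten feed, cumulative totals and any diagnostics.  If the reserve is
    exhausted the run is truncated with a diagnostic rather than raised.
    """
    core = params.core
    temp = TemperatureSeries(scenario.temperature)
    state0 = deb_core.initial_state_from_weight(
        scenario.initial_weight, scenario.f_initial, core)

    default_diet = next(iter(scenario.diets.values()))
    contexts = {name: DigestContext.build(d, params)
                for name, d in scenario.diets.items()}
    ctx = contexts[scenario.schedule.meals[0].diet_id] \
        if scenario.schedule.meals else contexts[next(iter(contexts))]

    # event times: meals + temperature breakpoints + end; all rounded to the
    # same 1e-12 d resolution as the output grid so coincident times compare
    # exactly equal
    meal_times = {round(m.time, 12): m for m in scenario.schedule.meals
                  if m.time < scenario.duration}
    breaks = sorted({0.0, round(scenario.duration, 12)}
                    | set(meal_times)
                    | {round(t, 12) for t in temp.breakpoints
                       if 0.0 < t < scenario.duration})

    grid = np.round(np.arange(0.0, scenario.duration * 24.0 + 0.5) / 24.0, 12)
    grid = grid[grid <= scenario.duration + 1e-12]

    y = np.array([state0.V, state0.E, state0.E_H, state0.E_R, 0.0,
                  0.0, 0.0, 0.0])   # + cum p_A, p_D, p_G (J per fish)
    rows: list[dict] = []
    meal_log: list[dict] = []
    diagnostics: list[str] = []
    terminated = False
    # per-hour uneaten/eaten mass bins
    eaten_bin = np.zeros(len(grid))
    uneaten_bin = np.zeros(len(grid))

    def rhs(t, y, ctx, T_K, c_T):
        V, E, E_H, E_R, M_X = y[:5]
        state = FishState(V=V, E=max(E, 0.0), E_H=E_H, E_R=max(E_R, 0.0))
        f_X = digestion.functional_response(max(M_X, 0.0), ctx.M_KX)
        fluxes = deb_core.deb_fluxes(state, f_X, T_K, core)
        dV, dE, dEH, dER = deb_core.state_derivatives(state, fluxes, core)
        s_M = deb_core.acceleration_factor(E_H, state.L, core)
        dMX = digestion.stomach_ode(max(M_X, 0.0), state.L, ctx.M_KX,
                                    ctx.yields, params.digestion,
                                    temp_factor=c_T, s_M=s_M)
        return [dV, dE, dEH, dER, dMX, fluxes.p_A, fluxes.p_D, fluxes.p_G]

    def reserve_exhausted(t, y, *args):
        return y[1]
    reserve_exhausted.terminal = True
    reserve_exhausted.direction = -1

    # puberty is a switching surface of the dynamics (dE_H -> 0, dE_R
    # switches on); crossing it inside a multistep integration stalls the
    # step-size control, so it is handled as a stop-clamp-restart event
    def puberty_crossing(t, y, *args):
        return y[2] - core.E_Hp
    puberty_crossing.terminal = True
    puberty_crossing.direction = 1

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        # meal event at segment start
        if t0 in meal_times:
            meal = meal_times[t0]
            ctx_in = contexts[meal.diet_id]
            if (ctx_in.diet is not ctx.diet) and y[4] > 1e-12:
                offered_probe = digestion.meal_intake(
                    y[4], y[0], _weight(y, core), meal.ration,
                    ctx_in.diet, params.digestion)
                pooled = _blend_diets(
                    ctx.diet, ctx_in.diet,
                    y[4] * ctx.diet.w_X, offered_probe.eaten * ctx_in.diet.w_X,
                    params)
                ctx = DigestContext.build(pooled, params)
                res = offered_probe
            else:
                ctx = ctx_in
                res = digestion.meal_intake(
                    y[4], y[0], _weight(y, core), meal.ration,
                    ctx.diet, params.digestion)
            y[4] += res.eaten
            hour_idx = min(int(np.floor(t0 * 24.0)), len(grid) - 1)
            eaten_bin[hour_idx] += res.eaten * ctx.diet.w_X
            uneaten_bin[hour_idx] += res.uneaten * ctx.diet.w_X
            meal_log.append({
                "time": t0, "diet": meal.diet_id,
                "offered_g": res.offered * ctx.diet.w_X,
                "eaten_g": res.eaten * ctx.diet.w_X,
                "uneaten_g": res.uneaten * ctx.diet.w_X,
            })

        T_K = temp.kelvin_at(t0)
        c_T = deb_core.temperature_factor(T_K, core)
        seg_eval = grid[(grid >= t0) & (grid < t1)]
        seg_start = t0
        while seg_start < t1 and not terminated:
            juvenile = y[2] < core.E_Hp
            events = [reserve_exhausted] + \
                ([puberty_crossing] if juvenile else [])
            t_eval = seg_eval[seg_eval >= seg_start]
            # sample the sub-segment start (post-meal) and hourly points
            sol = solve_ivp(rhs, (seg_start, t1), y, method="LSODA",
                            t_eval=np.unique(np.concatenate([t_eval, [t1]])),
                            args=(ctx, T_K, c_T), rtol=1e-8,
                            atol=[1e-10, 1e-6, 1e-8, 1e-8, 1e-14,
                                  1e-6, 1e-6, 1e-6],
                            events=events)
            if not sol.success:
                diagnostics.append(f"integrator failure in "
                                   f"[{seg_start}, {t1}]: {sol.message}")
                terminated = True
            for i, t in enumerate(sol.t):
                if t < t1 or (t1 == breaks[-1] and t == t1):
                    row = _instantaneous_rates(sol.y[:, i], T_K, ctx, params)
                    row["time"] = float(t)
                    rows.append(row)
            if sol.status == 1:
                if juvenile and len(sol.t_events[1]):
                    # puberty reached: clamp maturity and restart smoothly
                    t_pub = float(sol.t_events[1][0])
                    y = sol.y_events[1][0].copy()
                    y[2] = core.E_Hp
                    seg_start = t_pub
                    seg_eval = seg_eval[seg_eval > t_pub]
                    diagnostics.append(
                        f"puberty reached at t = {t_pub:.3f} d")
                    continue
                y = sol.y_events[0][0].copy()
                diagnostics.append(
                    f"reserve exhausted at t = {sol.t_events[0][0]:.3f} d; "
                    "run truncated (no starvation rules)")
                terminated = True
            else:
                y = sol.y[:, -1].copy()
            break
        if terminated:
            break

    hourly = pd.DataFrame(rows).drop_duplicates("time").sort_values("time")
    hourly = hourly.reset_index(drop=True)
    # per-meal masses as per-day-equivalent rates in the hour of the meal
    n = len(hourly)
    hourly["eaten_g"] = eaten_bin[:n]
    hourly["uneaten_g"] = uneaten_bin[:n]
    hourly["uneaten_g_per_d"] = hourly["uneaten_g"] * 24.0

    daily = aggregate_daily(hourly)
    meals_df = pd.DataFrame(
        meal_log, columns=["time", "diet", "offered_g", "eaten_g",
                           "uneaten_g"])
    cumulative = {
        "feed_offered_g": float(meals_df["offered_g"].sum()) if len(meals_df) else 0.0,
        "feed_eaten_g": float(meals_df["eaten_g"].sum()) if len(meals_df) else 0.0,
        "feed_uneaten_g": float(meals_df["uneaten_g"].sum()) if len(meals_df) else 0.0,
        "p_A_J": float(y[5]), "p_D_J": float(y[6]), "p_G_J": float(y[7]),
        "final_state": FishState(V=y[0], E=max(y[1], 0.0), E_H=y[2],
                                 E_R=max(y[3], 0.0)),
        "final_M_X_mol": float(max(y[4], 0.0)),
        "final_diet_context": ctx,
    }
    return SimulationOutput(hourly=hourly, daily=daily, meals=meals_df,
                            cumulative=cumulative, n_fish=scenario.n_fish,
                            diagnostics=diagnostics,
                            terminated_early=terminated)


def _weight(y: np.ndarray, core) -> float:
    state = FishState(V=y[0], E=max(y[1], 0.0), E_H=y[2], E_R=max(y[3], 0.0))
    return deb_core.wet_weight(state, core)


def aggregate_daily(hourly: pd.DataFrame) -> pd.DataFrame:
    """Daily series: mean of rate/state columns, sum of mass columns."""
    df = hourly.copy()
    df["day"] = np.floor(df["time"] + 1e-12).astype(int)
    agg = {c: "mean" for c in RATE_COLUMNS if c in df.columns}
    agg.update({c: "sum" for c in MASS_COLUMNS if c in df.columns})
    daily = df.groupby("day").agg(agg).reset_index()
    daily = daily.rename(columns={"day": "time"})
    return daily


# ---------------------------------------------------------------------------
# composition sweeps
# ---------------------------------------------------------------------------

def _sweep_diet(protein: float, fat_share: float, adc: dict,
                params: ModelParams) -> DietSpec:
    """Ash-free diet with given protein fraction and fat share of the rest."""
    non_protein = 1.0 - protein
    return diet_from_proximate(
        {"protein": protein, "fat": non_protein * fat_share,
         "carb": non_protein * (1.0 - fat_share), "ash": 0.0},
        adc, library=params.library, name="sweep")


def satiation_intake(diet: DietSpec, L: float, V: float, T_C: float,
                     params: ModelParams,
                     meals_per_day: int = 24) -> tuple[float, float]:
    """Steady daily intake and assimilation at satiation feeding, g/d.

    "Satiation" is operationalised as refilling the stomach to capacity at
    each of ``meals_per_day`` equally spaced meals; with the stomach reset to
    capacity at every meal the daily cycle is periodic immediately, so the
    intake per period is capacity minus the content left after one period,
    solved from the separable-ODE implicit form (no time stepping).

    Returns ``(intake, assimilation)`` in ash-free dry g/d (assimilation as
    dry reserve mass).  Single-substrate diets digest nothing and return
    ``(0, 0)``.
    """
    ctx = DigestContext.build(diet, params)
    if not np.isfinite(ctx.M_KX):
        return 0.0, 0.0
    c_T = deb_core.temperature_factor(T_C + KELVIN, params.core)
    s_M = params.core.s_M_max
    M0 = ctx.capacity_density * V
    k = (ctx.yields.total_food_per_reserve * params.digestion.J_EAm_d
         * s_M * c_T * L * L)
    tau = 1.0 / meals_per_day

    def implicit(M):
        return (M0 - M) + ctx.M_KX * np.log(M0 / M) - k * tau

    M_tau = brentq(implicit, 1e-300, M0, xtol=1e-15, rtol=1e-14)
    eaten_per_meal = M0 - M_tau
    intake = meals_per_day * eaten_per_meal * diet.w_X
    assim = (meals_per_day * eaten_per_meal
             / ctx.yields.total_food_per_reserve * params.core.w_Ed)
    return intake, assim


def diet_response_surface(protein_grid, fat_share_grid, fish_weight: float,
                          T_C: float, params: ModelParams,
                          adc: dict | None = None,
                          meals_per_day: int = 24,
                          f_assumed: float = 0.8) -> dict:
    """Satiation intake and assimilation over a composition grid.

    Returns ``{"protein", "fat_share", "intake", "assimilation"}`` with the
    two response arrays of shape (len(protein_grid), len(fat_share_grid)) in
    ash-free dry g/d.  Boundary compositions (protein 0 or 1) yield zeroes.
    """
    adc = adc or {"protein": 0.9, "fat": 0.9, "carb": 0.7}
    state = deb_core.initial_state_from_weight(fish_weight, f_assumed,
                                               params.core)
    protein_grid = np.asarray(protein_grid, dtype=float)
    fat_share_grid = np.asarray(fat_share_grid, dtype=float)
    intake = np.zeros((len(protein_grid), len(fat_share_grid)))
    assim = np.zeros_like(intake)
    for i, p in enumerate(protein_grid):
        for j, lam in enumerate(fat_share_grid):
            diet = _sweep_diet(p, lam, adc, params)
            intake[i, j], assim[i, j] = satiation_intake(
                diet, state.L, state.V, T_C, params, meals_per_day)
    return {"protein": protein_grid, "fat_share": fat_share_grid,
            "intake": intake, "assimilation": assim}


def intake_vs_energy(protein_levels, fat_share_grid, fish_weight: float,
                     T_C: float, params: ModelParams,
                     adc: dict | None = None,
                     meals_per_day: int = 24) -> pd.DataFrame:
    """Satiation intake against gross energy along fat-share sweeps.

    One curve per protein level; within each curve the fat share of the
    non-protein component increases, raising the gross energy density of the
    feed and lowering the satiation intake.
    """
    adc = adc or {"protein": 0.9, "fat": 0.9, "carb": 0.7}
    records = []
    for p in protein_levels:
        surf = diet_response_surface([p], fat_share_grid, fish_weight, T_C,
                                     params, adc, meals_per_day)
        for j, lam in enumerate(fat_share_grid):
            diet = _sweep_diet(p, lam, adc, params)
            records.append({
                "protein": p, "fat_share": lam,
                "gross_energy_kJ_per_g": diet.gross_energy,
                "intake_g_per_d": surf["intake"][0, j],
                "assimilation_g_per_d": surf["assimilation"][0, j],
            })
    return pd.DataFrame(records)
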