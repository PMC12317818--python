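"""Bundled default parameters and synthetic observation generators.

The default parameter set is a documented rainbow-trout-like fixture: a
coherent abj parameter set with magnitudes chosen so that a 150 g fish at
15 degC reaches satiation around 1-1.5 % body weight per day, empties a full
stomach over one to a few days, and grows at on-growing rates.  It is not
asserted to reproduce any database entry.  Synthetic observation sets
emulate the calibration experiments (gastric evacuation at several
temperatures and fish sizes; stomach water content against dry content;
growth trials) with multiplicative lognormal noise, and are byte-identical
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ObservationSet, evacuation_curve
from .deb_core import DEBCoreParams
from .digestion import DigestionParams
from .feed_chemistry import DietSpec, default_library, diet_from_proximate
from .params import ModelParams
from .simulation import Scenario, simulate

__all__ = [
    "FixtureConfig",
    "default_params",
    "default_diet",
    "synth_evacuation",
    "synth_water_content",
    "synth_growth_trial",
]

MU_E = 550_000.0   # J per C-mol reserve


@dataclass(frozen=True)
class FixtureConfig:
    """Design of a synthetic experiment.

    ``noise_sd`` is the standard deviation of multiplicative lognormal noise
    (observations are positive and heteroscedastic); set it to 0 for
    noise-free fixtures.  ``additive`` switches to additive Gaussian noise
    scaled by the mean observation.
    """

    seed: int = 0
    noise_sd: float = 0.05
    temperatures: tuple[float, ...] = (5.0, 10.0, 15.0)
    fish_sizes: tuple[float, ...] = (5.0, 20.0, 71.0)
    sampling_times: tuple[float, ...] = tuple(
        float(t) for t in (0.0417, 0.125, 0.25, 0.5, 0.75, 1.0, 1.5,
                           2.0, 3.0, 4.0, 6.0, 8.0))
    additive: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_params() -> ModelParams:
    """The bundled rainbow-trout-like parameter fixture.

    Core DEB abj values (J, cm, g, d at T_ref = 20 degC) paired with the
    digestion parameters; the moisturising coefficient defaults to 0.8425 g
    water per g dry food.  See docs/methods.md for how each magnitude was
    chosen.
    """
    core = DEBCoreParams(
        kappa=0.65, p_Am=1200.0, v=0.15, p_M=150.0, E_G=5220.0,
        k_J=0.002, kappa_R=0.95,
        E_Hb=30.0, E_Hj=600.0, E_Hp=3.0e5,
        T_A=8000.0, T_ref=293.15,
        L_b=0.35, L_j=0.77, L_p=5.5,
        mu_E=MU_E, w_Ed=23.9, d_Ed=0.30, d_Vw=1.0, d_Vd=0.20,
    )
    dig = DigestionParams(
        J_EAm_d=core.p_Am / core.mu_E,
        J_Xg_m=0.25, delta_g=0.10, y_HXd=0.8425, kappa_A=0.8,
    )
    return ModelParams(core=core, digestion=dig, library=default_library())


def default_diet(params: ModelParams | None = None) -> DietSpec:
    """The reference commercial feed: 45 % protein, 22 % fat, 19 %
    carbohydrate, 14 % ash (dry basis), ADC 0.9 / 0.9 / 0.7."""
    params = params or default_params()
    return diet_from_proximate(
        {"protein": 0.45, "fat": 0.22, "carb": 0.19, "ash": 0.14},
        {"protein": 0.9, "fat": 0.9, "carb": 0.7},
        library=params.library, name="reference")


def _perturb(values: np.ndarray, config: FixtureConfig,
             rng: np.random.Generator) -> np.ndarray:
    if config.noise_sd == 0:
        return values.copy()
    if config.additive:
        return values + config.noise_sd * np.mean(values) * \
            rng.standard_normal(len(values))
    return values * rng.lognormal(0.0, config.noise_sd, size=len(values))


def synth_evacuation(config: FixtureConfig, params: ModelParams,
                     diet: DietSpec) -> list[ObservationSet]:
    """Synthetic gastric-evacuation datasets, one per (temperature, size).

    Noiseless model curves (stomach content in % of the initial load) are
    sampled at the design times and perturbed by the noise model; the
    generating parameters are kept in ``truth`` for recovery tests.
    """
    rng = config.rng()
    out = []
    for T_C in config.temperatures:
        for W in config.fish_sizes:
            times = np.asarray(config.sampling_times)
            clean = evacuation_curve(W, T_C, times, params, diet)
            noisy = _perturb(clean, config, rng)
            records = pd.DataFrame({
                "covariate": times, "value": noisy,
                "units": "percent_initial", "T_C": T_C, "weight_g": W,
                "feeding_state": "postprandial",
            })
            out.append(ObservationSet(
                dataset_id=f"evac_T{T_C:g}_W{W:g}", kind="evacuation",
                records=records,
                truth={"J_Xg_m": params.digestion.J_Xg_m,
                       "J_EAm_d": params.digestion.J_EAm_d,
                       "clean": clean}))
    return out


def synth_water_content(config: FixtureConfig,
                        slope: float = 0.8425,
                        dry_mass_grid: np.ndarray | None = None,
                        noise_sd: float | None = None) -> ObservationSet:
    """Synthetic (dry stomach content, water content) pairs.

    Emulates the moisturising-line experiment: water = slope * dry mass with
    multiplicative scatter.  The default grid spans 0.1-5 g dry content with
    50 points and 3 % scatter, the resolution of a digitised regression line.
    """
    rng = config.rng()
    dry = dry_mass_grid if dry_mass_grid is not None \
        else np.linspace(0.1, 5.0, 50)
    sd = config.noise_sd if noise_sd is None else noise_sd
    water = slope * dry * rng.lognormal(0.0, sd, size=len(dry))
    records = pd.DataFrame({
        "covariate": dry, "value": water, "units": "g",
        "T_C": np.nan, "weight_g": np.nan, "feeding_state": "postprandial",
    })
    return ObservationSet(dataset_id="stomach_water", kind="stomach_water",
                          records=records, truth={"y_HXd": slope})


def synth_growth_trial(config: FixtureConfig, params: ModelParams,
                       scenario: Scenario,
                       sampling_days: np.ndarray | None = None
                       ) -> ObservationSet:
    """Synthetic weight time series from a simulated growth trial.

    The scenario is simulated once; weights at the sampling days are
    perturbed by the noise model.  The noiseless trajectory is kept in
    ``truth`` for recovery tests.
    """
    rng = config.rng()
    out = simulate(scenario, params)
    daily = out.daily
    days = sampling_days if sampling_days is not None \
        else np.arange(0, int(scenario.duration) + 1, 7)
    days = np.asarray([d for d in days if d in set(daily["time"])])
    clean = daily.set_index("time").loc[days, "W_g"].to_numpy()
    noisy = _perturb(clean, config, rng)
    records = pd.DataFrame({
        "covariate": days.astype(float), "value": noisy, "units": "g",
        "T_C": TemperatureMeta(scenario), "weight_g": scenario.initial_weight,
        "feeding_state": "fed",
    })
    return ObservationSet(dataset_id="growth_trial", kind="weight",
                          records=records,
                          truth={"clean": clean, "days": days,
                                 "output": out})


def TemperatureMeta(scenario: Scenario) -> float:
    """Scalar temperature metadata for a scenario (mean of the series)."""
    temp = scenario.temperature
    if np.isscalar(temp):
        return float(temp)
    return float(np.mean([v for _, v in temp]))
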