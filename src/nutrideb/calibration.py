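"""Error metrics, gastric-evacuation curves and digestion-parameter fitting.

The two goodness-of-fit measures are the mean relative error

    MRE = (1/n) * sum_i |xhat_i - x_i| / x_i

and the symmetric mean squared error

    SMSE = (1/n) * sum_i (xhat_i - x_i)^2 / (x_i^2 + xhat_i^2),

which is bounded in [0, 1] and symmetric under swapping observation and
prediction.  Calibration of the digestion parameters is a least-squares fit
of model evacuation / stomach-water predictions to observation sets,
minimising the sum of per-dataset normalised squared residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from . import deb_core, digestion
from .feed_chemistry import DietSpec
from .params import ModelParams
from .simulation import KELVIN, DigestContext

__all__ = [
    "ObservationSet",
    "mre",
    "smse",
    "evacuation_curve",
    "fit_digestion_params",
    "FitResult",
]

OBSERVATION_COLUMNS = ["dataset_id", "kind", "covariate", "value", "units",
                       "T_C", "weight_g", "feeding_state"]

FITTABLE = ("J_Xg_m", "J_EAm_d", "delta_g", "y_HXd")


@dataclass
class ObservationSet:
    """One calibration/validation dataset.

    ``kind`` is one of ``weight``, ``gas``, ``tan``, ``evacuation``,
    ``stomach_volume`` or ``stomach_water``; ``records`` holds one row per
    observation with the covariate (time for evacuation, dry mass for
    stomach-water pairs, ...), the observed value and condition metadata.
    """

    dataset_id: str
    kind: str
    records: pd.DataFrame
    truth: dict = field(default_factory=dict)   # generator ground truth

    def __post_init__(self) -> None:
        missing = [c for c in ("covariate", "value") if c not in self.records]
        if missing:
            raise ValueError(f"observation records lack columns {missing}")

    def to_csv(self, path_or_buf=None):
        df = self.records.copy()
        df.insert(0, "dataset_id", self.dataset_id)
        df.insert(1, "kind", self.kind)
        return df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> list["ObservationSet"]:
        df = pd.read_csv(path_or_buf)
        out = []
        for (ds, kind), grp in df.groupby(["dataset_id", "kind"]):
            out.append(cls(dataset_id=str(ds), kind=str(kind),
                           records=grp.drop(columns=["dataset_id", "kind"])
                           .reset_index(drop=True)))
        return out


def mre(observed, predicted) -> float:
    """Mean relative error; undefined (raises) for any zero observation."""
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(x == 0):
        raise ZeroDivisionError("MRE is undefined for zero observations")
    return float(np.mean(np.abs(xhat - x) / np.abs(x)))


def smse(observed, predicted) -> float:
    """Symmetric mean squared error, bounded in [0, 1]."""
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("observed and predicted must have equal length")
    denom = x ** 2 + xhat ** 2
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "SMSE is undefined where observation and prediction are both 0")
    return float(np.mean((xhat - x) ** 2 / denom))


def evacuation_curve(fish_weight: float, T_C: float, times,
                     params: ModelParams, diet: DietSpec,
                     initial_load: float = 1.0,
                     f_assumed: float = 0.8,
                     rtol: float = 1e-10) -> np.ndarray:
    """Stomach content in % of the initial amount at the requested times (d).

    The fish does not feed during the curve and growth over the window is
    neglected (structural length held fixed), matching how gastric
    evacuation trials are run; ``initial_load`` is the starting content as a
    fraction of the maximum stomach capacity.
    """
    if initial_load <= 0 or initial_load > 1:
        raise ValueError("initial_load must be in (0, 1]")
    state = deb_core.initial_state_from_weight(fish_weight, f_assumed,
                                               params.core)
    ctx = DigestContext.build(diet, params)
    M0 = initial_load * ctx.capacity_density * state.V
    c_T = deb_core.temperature_factor(T_C + KELVIN, params.core)
    s_M = deb_core.acceleration_factor(state.E_H, state.L, params.core)
    times = np.asarray(times, dtype=float)

    def rhs(t, y):
        return [digestion.stomach_ode(max(y[0], 0.0), state.L, ctx.M_KX,
                                      ctx.yields, params.digestion,
                                      temp_factor=c_T, s_M=s_M)]

    t_end = float(times.max()) if times.size else 0.0
    if t_end == 0.0:
        return np.full(times.shape, 100.0)
    sol = solve_ivp(rhs, (0.0, t_end), [M0],
                    t_eval=np.unique(np.concatenate([[0.0], times])),
                    method="LSODA", rtol=rtol, atol=M0 * 1e-12)
    lookup = dict(zip(sol.t, sol.y[0]))
    return np.array([100.0 * max(lookup[t], 0.0) / M0 for t in times])


@dataclass
class FitResult:
    """Least-squares calibration outcome."""

    estimates: dict
    success: bool
    cost: float
    report: pd.DataFrame          # per-dataset MRE / SMSE
    message: str = ""
    warnings: list = field(default_factory=list)


def _predict(obs: ObservationSet, params: ModelParams,
             diet: DietSpec) -> np.ndarray:
    if obs.kind == "evacuation":
        load = float(obs.records.get("initial_load", pd.Series([1.0])).iloc[0]) \
            if "initial_load" in obs.records else 1.0
        return evacuation_curve(
            fish_weight=float(obs.records["weight_g"].iloc[0]),
            T_C=float(obs.records["T_C"].iloc[0]),
            times=obs.records["covariate"].to_numpy(),
            params=params, diet=diet, initial_load=load, rtol=1e-8)
    if obs.kind == "stomach_water":
        # water (g) added to moisturise the observed dry mass (g)
        return params.digestion.y_HXd * obs.records["covariate"].to_numpy()
    raise NotImplementedError(
        f"no predictor for observation kind '{obs.kind}'")


def fit_digestion_params(datasets: list[ObservationSet],
                         free: tuple[str, ...],
                         params: ModelParams,
                         diet: DietSpec,
                         weights: dict | None = None) -> FitResult:
    """Least-squares calibration of digestion parameters.

    ``free`` names the subset of digestion parameters to estimate
    (``J_Xg_m``, ``J_EAm_d``, ``delta_g``, ``y_HXd``); the rest stay fixed.
    Parameters are fitted on a log scale (all are positive rates or ratios).
    The objective is the sum over datasets of squared residuals normalised
    by the dataset mean, optionally weighted per dataset.  The optimiser is
    deterministic (trust-region reflective from the current parameter
    values), so results are reproducible without a seed.

    A finite-difference sensitivity check warns when the Jacobian at the
    optimum is rank-deficient (unidentifiable subset).
    """
    if not datasets:
        raise ValueError("at least one observation set is required")
    unknown = [f for f in free if f not in FITTABLE]
    if unknown:
        raise ValueError(f"cannot fit {unknown}; fittable: {FITTABLE}")
    weights = weights or {}

    def with_values(theta_log: np.ndarray) -> ModelParams:
        updates = {name: math.exp(v) for name, v in zip(free, theta_log)}
        dig = replace(params.digestion, **updates)
        core = params.core
        if "J_EAm_d" in updates:
            core = replace(core, p_Am=updates["J_EAm_d"] * core.mu_E)
        return ModelParams(core=core, digestion=dig, library=params.library)

    def residuals(theta_log: np.ndarray) -> np.ndarray:
        p = with_values(theta_log)
        res = []
        for obs in datasets:
            pred = _predict(obs, p, diet)
            x = obs.records["value"].to_numpy(dtype=float)
            w = weights.get(obs.dataset_id, 1.0)
            scale = np.mean(np.abs(x))
            res.append(np.sqrt(w) * (pred - x) / scale)
        return np.concatenate(res)

    x0 = np.array([math.log(getattr(params.digestion, f)) for f in free])
    fit = least_squares(residuals, x0, method="trf", x_scale="jac",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)

    warn_list = []
    if len(free) > 1:
        jac = fit.jac
        sv = np.linalg.svd(jac, compute_uv=False)
        if sv[-1] < 1e-8 * sv[0]:
            msg = (f"parameter subset {free} appears unidentifiable "
                   f"(Jacobian condition {sv[0] / max(sv[-1], 1e-300):.2g})")
            warn_list.append(msg)
            warnings.warn(msg)

    fitted = with_values(fit.x)
    rows = []
    for obs in datasets:
        pred = _predict(obs, fitted, diet)
        x = obs.records["value"].to_numpy(dtype=float)
        ok = np.all(x != 0)
        rows.append({
            "dataset_id": obs.dataset_id, "kind": obs.kind, "n": len(x),
            "mre": mre(x, pred) if ok else np.nan,
            "smse": smse(x, pred),
        })
    estimates = {name: math.exp(v) for name, v in zip(free, fit.x)}
    message = fit.message if fit.success else \
        f"non-convergence, best-so-far returned: {fit.message}"
    return FitResult(estimates=estimates, success=bool(fit.success),
                     cost=float(fit.cost), report=pd.DataFrame(rows),
                     message=message, warnings=warn_list)
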