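"""Standard DEB abj state dynamics.

State of one fish: structural volume ``V`` (cm^3), reserve energy ``E`` (J),
cumulative maturity ``E_H`` (J) and the reproduction buffer ``E_R`` (J).
Reserve is mobilised according to the kappa-rule: a fixed fraction ``kappa``
of the mobilised power pays somatic maintenance and growth, the remainder
pays maturity maintenance and maturation (juveniles) or reproduction
(adults).  Between birth and metamorphosis the surface-specific assimilation
rate and the energy conductance accelerate with length (abj model); a single
Arrhenius factor corrects all rates for temperature.

Units are fixed at J, mol, cm, g, d throughout; conversions happen at the
I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DEBCoreParams",
    "FishState",
    "Powers",
    "StarvationError",
    "temperature_factor",
    "acceleration_factor",
    "deb_fluxes",
    "state_derivatives",
    "wet_weight",
    "initial_state_from_weight",
    "von_bertalanffy_rate",
    "integrate_constant_f",
]


class StarvationError(RuntimeError):
    """Reserve cannot pay maintenance; the run must stop with a diagnostic."""


@dataclass(frozen=True)
class DEBCoreParams:
    """Core DEB abj parameters (AmP-style naming, see docs/methods.md).

    Rates (``p_Am``, ``v``, ``p_M``, ``k_J``) are at the reference
    temperature ``T_ref`` and, for the surface-specific ones, before
    metabolic acceleration.
    """

    kappa: float          # allocation fraction to soma, -
    p_Am: float           # surface-specific max assimilation power, J/d/cm^2
    v: float              # energy conductance, cm/d
    p_M: float            # volume-specific somatic maintenance, J/d/cm^3
    E_G: float            # volume-specific cost of structure, J/cm^3
    k_J: float            # maturity maintenance rate coefficient, 1/d
    kappa_R: float        # reproduction efficiency, -
    E_Hb: float           # maturity at birth, J
    E_Hj: float           # maturity at metamorphosis, J
    E_Hp: float           # maturity at puberty, J
    T_A: float            # Arrhenius temperature, K
    T_ref: float          # reference temperature, K
    L_b: float            # structural length at birth, cm
    L_j: float            # structural length at metamorphosis, cm
    L_p: float            # structural length at puberty, cm (init heuristic)
    mu_E: float           # chemical potential of reserve, J/mol
    w_Ed: float           # molar weight of dry reserve, g/mol
    d_Ed: float           # g dry reserve per cm^3 reserve volume
    d_Vw: float           # wet specific density of structure, g/cm^3
    d_Vd: float           # dry specific density of structure, g/cm^3

    def __post_init__(self) -> None:
        if not 0 < self.kappa < 1:
            raise ValueError(f"kappa must lie in (0, 1), got {self.kappa}")
        if not (self.E_Hb < self.E_Hj < self.E_Hp):
            raise ValueError("maturity thresholds must satisfy E_Hb < E_Hj < E_Hp")
        if not (0 < self.L_b < self.L_j):
            raise ValueError("must have 0 < L_b < L_j")
        for name in ("p_Am", "v", "p_M", "E_G", "k_J", "T_A", "T_ref",
                     "mu_E", "w_Ed", "d_Ed", "d_Vw", "d_Vd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def s_M_max(self) -> float:
        """Acceleration factor after metamorphosis, L_j / L_b."""
        return self.L_j / self.L_b

    @property
    def E_m(self) -> float:
        """Maximum reserve density [E_m] = p_Am / v, J/cm^3 (s_M cancels)."""
        return self.p_Am / self.v

    @property
    def omega(self) -> float:
        """Reserve contribution to wet weight at e = 1, relative to d_Vw*V."""
        return self.E_m * self.w_Ed / (self.d_Ed * self.mu_E)

    def L_m(self, s_M: float | None = None) -> float:
        """Maximum structural length kappa*p_Am*s_M/p_M, cm."""
        s = self.s_M_max if s_M is None else s_M
        return self.kappa * self.p_Am * s / self.p_M


@dataclass
class FishState:
    """State variables of one fish (stomach content lives in the scenario)."""

    V: float
    E: float
    E_H: float
    E_R: float = 0.0
    L_j_realized: float | None = None   # length recorded at metamorphosis

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"structural volume must be positive, got {self.V}")
        if self.E < 0 or self.E_H < 0 or self.E_R < 0:
            raise ValueError("energies must be non-negative")

    @property
    def L(self) -> float:
        return self.V ** (1.0 / 3.0)


class Powers(NamedTuple):
    """Energy fluxes, J/d."""

    p_A: float
    p_C: float
    p_S: float
    p_J: float
    p_G: float
    p_R: float
    p_D: float
    starving: bool


def temperature_factor(T: float, params: DEBCoreParams) -> float:
    """Arrhenius correction exp(T_A/T_ref - T_A/T); equals 1 at T_ref."""
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return math.exp(params.T_A / params.T_ref - params.T_A / T)


def acceleration_factor(E_H: float, L: float, params: DEBCoreParams,
                        L_j_realized: float | None = None) -> float:
    """Metabolic acceleration s_M of the abj model.

    1 before birth; L/L_b between birth and metamorphosis; frozen at
    L_j/L_b afterwards (using the realized metamorphosis length when a
    simulation crossed the threshold itself).
    """
    if E_H < params.E_Hb:
        return 1.0
    if E_H < params.E_Hj:
        return max(1.0, L / params.L_b)
    L_j = L_j_realized if L_j_realized is not None else params.L_j
    return L_j / params.L_b


def deb_fluxes(state: FishState, f_X: float, T: float,
               params: DEBCoreParams) -> Powers:
    """Energy fluxes of the kappa-rule allocation at temperature ``T`` (K).

    ``f_X`` is the scaled functional response supplied by the digestion
    module.  Somatic maintenance has priority: if ``kappa*p_C`` falls short
    of it, growth is zero and the shortfall is paid from the maturity
    branch (no shrinking rules); if even that fails, ``starving`` is set.
    The returned fluxes satisfy ``p_C = p_S + p_J + p_G + p_R`` exactly at
    every non-terminal step.
    """
    c_T = temperature_factor(T, params)
    s_M = acceleration_factor(state.E_H, state.L, params, state.L_j_realized)
    V, L = state.V, state.L

    p_A = params.p_Am * s_M * c_T * f_X * L * L
    p_S = params.p_M * c_T * V
    p_J = params.k_J * c_T * min(state.E_H, params.E_Hp)

    E_density = state.E / V
    p_C = (E_density
           * (params.E_G * params.v * s_M * c_T * L * L + p_S)
           / (params.E_G + params.kappa * E_density))

    p_G = params.kappa * p_C - p_S
    p_R = (1.0 - params.kappa) * p_C - p_J
    starving = False
    if p_G < 0:                       # somatic maintenance shortfall
        p_R += p_G                    # paid from the maturity branch
        p_G = 0.0
        starving = True
    if p_R < 0:
        p_G += p_R                    # maturity maintenance from soma branch
        p_R = 0.0
        starving = True
        if p_G < 0:
            # mobilisation cannot cover maintenance: pay it straight from
            # reserve (faster drain than the weak-homeostasis p_C), no
            # growth, no maturation; the run ends when E reaches zero
            p_G = 0.0
            p_C = p_S + p_J

    adult = state.E_H >= params.E_Hp
    if adult:
        p_D = p_S + p_J + (1.0 - params.kappa_R) * p_R
    else:
        p_D = p_S + p_J + p_R
    return Powers(p_A=p_A, p_C=p_C, p_S=p_S, p_J=p_J, p_G=p_G, p_R=p_R,
                  p_D=p_D, starving=starving)


def state_derivatives(state: FishState, fluxes: Powers,
                      params: DEBCoreParams) -> tuple[float, float, float, float]:
    """(dV, dE, dE_H, dE_R) per day from the energy fluxes."""
    dV = fluxes.p_G / params.E_G
    dE = fluxes.p_A - fluxes.p_C
    if state.E_H < params.E_Hp:
        return dV, dE, fluxes.p_R, 0.0
    return dV, dE, 0.0, params.kappa_R * fluxes.p_R


def wet_weight(state: FishState, params: DEBCoreParams) -> float:
    """Wet body weight, g: W = d_Vw*V + (E + E_R)*w_Ed/(d_Ed*mu_E).

    Stomach content is excluded — the gut is treated as external environment.
    """
    return (params.d_Vw * state.V
            + (state.E + state.E_R) * params.w_Ed / (params.d_Ed * params.mu_E))


def initial_state_from_weight(W0: float, f_assumed: float,
                              params: DEBCoreParams) -> FishState:
    """Construct a fish state of wet weight ``W0`` at reserve density e = f.

    The reserve is set to its equilibrium density ``f * [E_m]`` and V solved
    from the wet-weight relation.  Maturity is assigned from structural
    length: adults (L >= L_p) sit at E_Hp; between metamorphosis and puberty
    maturity is interpolated cubically in L (a documented heuristic — only
    the small maturity-maintenance flux depends on it); below L_j the fish is
    mid-acceleration.  The reproduction buffer starts empty.
    """
    if W0 <= 0:
        raise ValueError(f"initial weight must be positive, got {W0}")
    if not 0 < f_assumed <= 1:
        raise ValueError(f"f_assumed must be in (0, 1], got {f_assumed}")

    density_term = params.d_Vw + f_assumed * params.E_m * params.w_Ed / (
        params.d_Ed * params.mu_E)
    V = W0 / density_term
    L = V ** (1.0 / 3.0)
    W_b = params.L_b ** 3 * density_term
    if W0 < W_b:
        raise ValueError(
            f"initial weight {W0} g is below the weight at birth ({W_b:.3g} g)")

    if L >= params.L_p:
        E_H = params.E_Hp
    elif L >= params.L_j:
        x = (L - params.L_j) / (params.L_p - params.L_j)
        E_H = params.E_Hj + (params.E_Hp - params.E_Hj) * x ** 3
    else:
        x = (L - params.L_b) / (params.L_j - params.L_b)
        E_H = params.E_Hb + (params.E_Hj - params.E_Hb) * max(x, 0.0) ** 3
    E = f_assumed * params.E_m * V
    return FishState(V=V, E=E, E_H=E_H, E_R=0.0)


def von_bertalanffy_rate(f: float, T: float, params: DEBCoreParams,
                         s_M: float | None = None) -> tuple[float, float]:
    """(r_B, L_inf) of the classical von Bertalanffy limit at constant f, T.

    ``r_B = 1 / (3/k_M + 3 f L_m / v_s)`` with ``k_M = p_M c_T / E_G`` and
    ``v_s = v s_M c_T``; ``L_inf = f L_m``.  Valid post-metamorphosis at
    reserve-density equilibrium e = f.
    """
    c_T = temperature_factor(T, params)
    s = params.s_M_max if s_M is None else s_M
    k_M = params.p_M * c_T / params.E_G
    v_s = params.v * s * c_T
    L_m = params.L_m(s)
    r_B = 1.0 / (3.0 / k_M + 3.0 * f * L_m / v_s)
    return r_B, f * L_m


def integrate_constant_f(state: FishState, f: float, T: float,
                         params: DEBCoreParams, duration: float,
                         t_eval: np.ndarray | None = None,
                         rtol: float = 1e-10):
    """Integrate the DEB state at constant functional response and temperature.

    Used for the von Bertalanffy cross-check and for quick growth estimates
    that bypass the stomach dynamics.  Returns the scipy OdeResult with rows
    (V, E, E_H, E_R).
    """

    def rhs(t, y):
        s = FishState(V=y[0], E=max(y[1], 0.0), E_H=y[2], E_R=y[3],
                      L_j_realized=state.L_j_realized)
        fluxes = deb_fluxes(s, f, T, params)
        dV, dE, dEH, dER = state_derivatives(s, fluxes, params)
        return [dV, dE, dEH, dER]

    y0 = [state.V, state.E, state.E_H, state.E_R]
    return solve_ivp(rhs, (0.0, duration), y0, method="LSODA",
                     t_eval=t_eval, rtol=rtol, atol=1e-10)
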