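"""Digestion–assimilation kinetics and stomach dynamics.

The whole alimentary tract is consolidated into a single "stomach"
compartment holding ``M_X`` C-mol of ash-free dry food.  Digestion proceeds
at a rate proportional to the digestive surface (structural length squared)
and to the stomach content; absorption and reserve synthesis follow the
parallel-complementary synthesising-unit (SU) kinetics in which the protein
and non-protein substrates are both required to build reserve.  Meals are
instantaneous jumps of ``M_X`` clipped at the moisture-corrected maximum
stomach capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .feed_chemistry import CouplingYields, DietSpec

__all__ = [
    "DigestionParams",
    "StomachState",
    "MealResult",
    "max_stomach_capacity",
    "half_saturation",
    "functional_response",
    "assimilation_flux",
    "substrate_and_faeces_fluxes",
    "meal_intake",
    "stomach_ode",
]

#: density of water, g/cm^3
D_WATER = 1.0


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of the digestion–assimilation module.

    Attributes
    ----------
    J_EAm_d : float
        Surface-specific maximum assimilation rate, mol reserve / (d cm^2),
        at the reference temperature and before metabolic acceleration.
    J_Xg_m : float
        Surface-specific maximum digestion rate coefficient, 1 / (d cm^2):
        the digestion rate is ``J_Xg_m * L^2 * M_X``.
    delta_g : float
        Stomach shape coefficient (stomach volume = delta_g * V).
    y_HXd : float
        Moisturising coefficient: g water added in the stomach per g of
        ingested dry food (default 0.8425).
    kappa_A : float
        Reserve yield on absorbed substrate carbon (C-mol reserve per C-mol
        absorbed); the remainder is respired as assimilation CO2.
    """

    J_EAm_d: float
    J_Xg_m: float
    delta_g: float
    y_HXd: float = 0.8425
    kappa_A: float = 0.8

    def __post_init__(self) -> None:
        for name in ("J_EAm_d", "J_Xg_m", "delta_g", "y_HXd", "kappa_A"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class StomachState:
    """Ash-free dry food in the stomach (C-mol) and its resident diet."""

    M_X: float
    diet: DietSpec

    def __post_init__(self) -> None:
        if self.M_X < 0:
            raise ValueError(f"stomach content cannot be negative: {self.M_X}")


def max_stomach_capacity(diet: DietSpec, params: DigestionParams) -> float:
    """Volume-specific maximum stomach capacity [M_gm], mol/cm^3.

    At capacity the volume of the dry food plus the water that moisturises it
    fills the stomach volume ``delta_g * V``::

        [M_gm] = (y_HXd * d_Xd / d_H + 1)^-1 * (d_Xd / w_X) * delta_g

    so the capacity depends on the feed's density and C-molar weight as well
    as on stomach geometry.
    """
    water_term = params.y_HXd * diet.d_Xd / D_WATER
    return (1.0 / (water_term + 1.0)) * diet.d_Xd / diet.w_X * params.delta_g


def half_saturation(diet: DietSpec, yields: CouplingYields,
                    params: DigestionParams) -> float:
    """Half-saturation stomach content M_KX (mol) of the SU kinetics.

    With ``A = q_P/a_P`` and ``B = q_nP/(1 - a_P)``::

        M_KX = (J_EAm_d / J_Xg_m) * (A + B - (1/A + 1/B)^-1)

    Both surface-specific rates carry the same temperature and acceleration
    factors, so their ratio — and hence M_KX — is independent of both.  At
    ``a_P`` of exactly 0 or 1 the missing complementary substrate makes the
    half-saturation infinite (assimilation nullified), returned as ``inf``
    rather than raised, so that composition sweeps run unattended.
    """
    a_P = diet.a_P
    if a_P <= 0.0 or a_P >= 1.0:
        return math.inf
    A = yields.q_P / a_P
    B = yields.q_nP / (1.0 - a_P)
    su = A + B - 1.0 / (1.0 / A + 1.0 / B)
    return params.J_EAm_d / params.J_Xg_m * su


def functional_response(M_X: float, M_KX: float) -> float:
    """Scaled functional response for digestion, f_X = M_X/(M_X + M_KX)."""
    if M_X <= 0.0:
        return 0.0
    if math.isinf(M_KX):
        return 0.0
    return M_X / (M_X + M_KX)


def assimilation_flux(f_X: float, L: float, params: DigestionParams,
                      mu_E: float, temp_factor: float = 1.0,
                      s_M: float = 1.0) -> tuple[float, float]:
    """Reserve-formation rate J_EA (mol/d) and assimilation power p_A (J/d).

    ``J_EA = J_EAm_d * s_M * c_T * f_X * L^2``; the acceleration factor and
    the Arrhenius correction scale the surface-specific rate.
    """
    J_EA = params.J_EAm_d * s_M * temp_factor * f_X * L * L
    return J_EA, mu_E * J_EA


def substrate_and_faeces_fluxes(J_EA: float, yields: CouplingYields
                                ) -> tuple[float, float, float]:
    """Stomach outflows coupled to reserve formation (mol/d).

    Returns ``(J_XP+, J_XnP+, J_P)``: protein substrate, non-protein substrate
    and faeces, all proportional to ``J_EA``.
    """
    return yields.q_P * J_EA, yields.q_nP * J_EA, yields.y_PE * J_EA


@dataclass(frozen=True)
class MealResult:
    """Outcome of one discrete meal (all amounts in C-mol ash-free dry food)."""

    offered: float
    eaten: float

    @property
    def uneaten(self) -> float:
        return self.offered - self.eaten


def meal_intake(M_X: float, V: float, W: float, k_X: float,
                diet: DietSpec, params: DigestionParams) -> MealResult:
    """Instantaneous meal intake, clipped at stomach capacity.

    ``k_X`` is the meal ration as a fraction of wet body weight ``W`` (g).
    The amount eaten is the minimum of the stomach deficit and the offered
    feed converted to C-mol of ash-free dry matter::

        eaten = min([M_gm] V - M_X, k_X * (d_Xd/d_Xw) * W / w_X)

    Offered-minus-eaten is the wasted (uneaten) feed.
    """
    if k_X < 0:
        raise ValueError(f"meal ration must be non-negative, got {k_X}")
    offered = k_X * diet.dry_to_wet * W / diet.w_X
    deficit = max_stomach_capacity(diet, params) * V - M_X
    if deficit < 0:          # numerical overshoot of the integrator
        deficit = 0.0
    eaten = min(deficit, offered)
    return MealResult(offered=offered, eaten=eaten)


def stomach_ode(M_X: float, L: float, M_KX: float, yields: CouplingYields,
                params: DigestionParams, temp_factor: float = 1.0,
                s_M: float = 1.0) -> float:
    """Rate of change of stomach content between meals, mol/d.

    ``dM_X/dt = -(q_P + q_nP + y_PE) * J_EAm_d * s_M * c_T * f_X * L^2`` —
    the food absorbed to form reserve plus that lost as faeces.  Strictly
    negative while the stomach holds food, zero when empty.
    """
    f_X = functional_response(M_X, M_KX)
    return -(yields.total_food_per_reserve
             * params.J_EAm_d * s_M * temp_factor * f_X * L * L)
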