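"""Elemental C/H/O/N mass balance and mineral fluxes.

Every mass flux of a mineral compound (O2, CO2, H2O, ammonia) is a weighted
sum of the three basic powers — assimilation ``p_A``, dissipation ``p_D`` and
growth ``p_G``.  The weights follow from the element balance of the organic
fluxes each power drives: assimilation consumes the two food substrates and
produces reserve plus faeces; dissipation burns reserve; growth converts
reserve into structure.  For each power the four mineral fluxes are the
unique solution of the 4x4 linear system that zeroes the C, H, O and N
totals, so elemental conservation holds to machine precision at every step.

With the nitrogen-exact coupling yields of :mod:`nutrideb.feed_chemistry`
the ammonia coefficient of assimilation is zero, hence the reported TAN is
``J_N = eta_ND p_D + eta_NG p_G`` (a config flag can re-enable the
assimilation term for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deb_core import DEBCoreParams
from .feed_chemistry import CompoundComposition, CouplingYields, DietSpec

__all__ = [
    "EtaMatrix",
    "WasteRates",
    "MINERAL_ORDER",
    "eta_matrix",
    "mineral_fluxes",
    "faecal_nitrogen",
    "solid_waste",
    "GRAMS_PER_MOL",
]

#: column order of the mineral compounds in the balance matrices
MINERAL_ORDER = ("CO2", "H2O", "O2", "NH3")

#: element rows C, H, O, N for the mineral compounds
_N_MINERAL = np.array([
    #  CO2  H2O  O2  NH3
    [1.0, 0.0, 0.0, 0.0],   # C
    [0.0, 2.0, 0.0, 3.0],   # H
    [2.0, 1.0, 2.0, 0.0],   # O
    [0.0, 0.0, 0.0, 1.0],   # N
])

GRAMS_PER_MOL = {"O2": 32.0, "CO2": 44.0, "N": 14.0}


def _element_matrix(comps: list[CompoundComposition]) -> np.ndarray:
    """Rows C,H,O,N; one column per organic compound."""
    return np.array([[1.0] * len(comps),
                     [c.n_H for c in comps],
                     [c.n_O for c in comps],
                     [c.n_N for c in comps]])


@dataclass(frozen=True)
class EtaMatrix:
    """Mineral-flux coefficients per unit power, mol/J.

    ``eta[mineral][power]`` with minerals CO2/H2O/O2/NH3 (O2 positive as
    consumption, others positive as production) and powers A/D/G.
    """

    eta_OA: float
    eta_OD: float
    eta_OG: float
    eta_CA: float
    eta_CD: float
    eta_CG: float
    eta_NA: float   # ~0 under the default nitrogen-exact yield closure
    eta_ND: float
    eta_NG: float
    eta_HA: float
    eta_HD: float
    eta_HG: float
    include_assimilation_n: bool = False

    def as_array(self) -> np.ndarray:
        """(4 minerals x 3 powers) array in MINERAL_ORDER, production-positive
        (O2 negative = consumption), for audits."""
        return np.array([
            [self.eta_CA, self.eta_CD, self.eta_CG],
            [self.eta_HA, self.eta_HD, self.eta_HG],
            [-self.eta_OA, -self.eta_OD, -self.eta_OG],
            [self.eta_NA, self.eta_ND, self.eta_NG],
        ])


def organic_flux_matrix(yields: CouplingYields,
                        structure: CompoundComposition,
                        params: DEBCoreParams) -> np.ndarray:
    """Organic compound fluxes per unit power, mol/J.

    Rows: X_P, X_nP, E, V, P (consumption negative); columns: p_A, p_D, p_G.
    """
    mu_E = params.mu_E
    y_VG = structure_moles_per_joule(params, structure)
    # assimilation drains the stomach of the whole ingested substrate
    # (absorbed + indigestible), so the food rows carry the ingested totals
    # while the faeces row returns the indigestible share
    return np.array([
        [-yields.ingested_P / mu_E, 0.0, 0.0],
        [-yields.ingested_nP / mu_E, 0.0, 0.0],
        [1.0 / mu_E, -1.0 / mu_E, -1.0 / mu_E],
        [0.0, 0.0, y_VG],
        [yields.y_PE / mu_E, 0.0, 0.0],
    ])


def eta_matrix(diet: DietSpec, yields: CouplingYields,
               reserve: CompoundComposition, structure: CompoundComposition,
               params: DEBCoreParams,
               include_assimilation_n: bool = False) -> EtaMatrix:
    """Solve the 4-element balance for the mineral coefficients of each power.

    Raises a descriptive error if a degenerate composition makes the balance
    singular (cannot happen with the fixed CO2/H2O/O2/NH3 mineral set, whose
    matrix is invertible, but organic compositions are validated here).
    """
    organics = [diet.comp_XP, diet.comp_XnP, reserve, structure, yields.comp_P]
    names = ["food protein", "food non-protein", "reserve", "structure",
             "faeces"]
    for comp, name in zip(organics, names):
        if comp.w <= 0:
            raise ValueError(f"degenerate composition for {name}")

    n_org = _element_matrix(organics)
    j_org = organic_flux_matrix(yields, structure, params)
    # mineral fluxes that zero each element row, production positive
    j_min = -np.linalg.solve(_N_MINERAL, n_org @ j_org)
    co2, h2o, o2, nh3 = j_min          # rows in MINERAL_ORDER

    return EtaMatrix(
        eta_OA=-o2[0], eta_OD=-o2[1], eta_OG=-o2[2],   # consumption positive
        eta_CA=co2[0], eta_CD=co2[1], eta_CG=co2[2],
        eta_NA=nh3[0], eta_ND=nh3[1], eta_NG=nh3[2],
        eta_HA=h2o[0], eta_HD=h2o[1], eta_HG=h2o[2],
        include_assimilation_n=include_assimilation_n,
    )


def structure_moles_per_joule(params: DEBCoreParams,
                              structure: CompoundComposition) -> float:
    """C-mol of structure built per J of growth power, [M_V]/E_G."""
    return params.d_Vd / structure.w / params.E_G


@dataclass(frozen=True)
class WasteRates:
    """Reported waste fluxes (consumption/production positive)."""

    J_O: float           # mol O2/d consumed
    J_C: float           # mol CO2/d produced
    J_N: float           # mol TAN-N/d (non-faecal)
    J_PN: float          # g N/d lost via faeces
    faeces_dry: float    # g/d dry faeces (organic + ash)

    @property
    def J_O_g(self) -> float:
        return self.J_O * GRAMS_PER_MOL["O2"]

    @property
    def J_C_g(self) -> float:
        return self.J_C * GRAMS_PER_MOL["CO2"]

    @property
    def J_N_g(self) -> float:
        return self.J_N * GRAMS_PER_MOL["N"]


def mineral_fluxes(p_A: float, p_D: float, p_G: float,
                   eta: EtaMatrix) -> tuple[float, float, float]:
    """(J_O, J_C, J_N) in mol/d from the three basic powers (J/d).

    ``J_N`` omits the assimilation term (zero under the default yield
    closure) unless ``eta.include_assimilation_n`` is set.
    """
    J_O = eta.eta_OA * p_A + eta.eta_OD * p_D + eta.eta_OG * p_G
    J_C = eta.eta_CA * p_A + eta.eta_CD * p_D + eta.eta_CG * p_G
    J_N = eta.eta_ND * p_D + eta.eta_NG * p_G
    if eta.include_assimilation_n:
        J_N += eta.eta_NA * p_A
    return J_O, J_C, J_N


def faecal_nitrogen(p_A: float, yields: CouplingYields,
                    params: DEBCoreParams) -> float:
    """Nitrogen lost via faeces, g N/d: J_PN = 14 n_NP y_PE p_A / mu_E."""
    if p_A < 0:
        raise ValueError(f"assimilation power cannot be negative: {p_A}")
    return (GRAMS_PER_MOL["N"] * yields.comp_P.n_N * yields.y_PE
            * p_A / params.mu_E)


def solid_waste(J_P: float, diet: DietSpec, yields: CouplingYields,
                food_outflow: float) -> float:
    """Dry faecal solids, g/d: organic faeces plus the inert ash ride-along.

    ``J_P`` is the faeces production (mol C/d) and ``food_outflow`` the total
    C-mol/d of ash-free food leaving the stomach, which carries
    ``ash_per_cmol`` grams of ash per C-mol straight to the faeces.
    """
    if J_P < 0:
        raise ValueError(f"faeces production cannot be negative: {J_P}")
    return J_P * yields.comp_P.w + food_outflow * diet.ash_per_cmol
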