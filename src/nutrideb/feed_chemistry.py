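"""Chemical description of feeds for the nutritional DEB model.

All organic compounds (food protein and non-protein substrates, reserve,
structure, faeces) are treated as generalised compounds with one carbon atom
per "molecule": CH_{n_H} O_{n_O} N_{n_N}.  A proximate feed analysis
(protein / fat / carbohydrate / ash mass fractions of dry matter) is converted
into the C-mol description the digestion and mass-balance modules work with:
the protein C-mol fraction ``a_P``, the chemical indices of the two food
substrates, the stoichiometric coupling yields of reserve synthesis and the
faeces composition that closes the elemental balance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

__all__ = [
    "ATOMIC_WEIGHTS",
    "CompoundComposition",
    "DietSpec",
    "CouplingYields",
    "InvalidCompositionError",
    "DegenerateDietError",
    "build_compound_library",
    "default_library",
    "diet_from_proximate",
    "gross_energy_density",
    "coupling_yields",
    "DEFAULT_COMBUSTION_KJ_PER_G",
]

#: g/mol of C, H, O, N — the only elements tracked by the model.
ATOMIC_WEIGHTS = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0}


class InvalidCompositionError(ValueError):
    """A chemical composition violates its invariants."""


class DegenerateDietError(ValueError):
    """The diet contains no digestible organic matter (e.g. all ash)."""


@dataclass(frozen=True)
class CompoundComposition:
    """Generalised compound CH_{n_H} O_{n_O} N_{n_N} on a C-mol basis.

    Parameters
    ----------
    n_H, n_O, n_N : float
        Chemical indices: mol H, O, N per mol C.
    mu : float
        Chemical potential, J per C-mol.
    d : float
        Specific density, g/cm^3 (dry-matter basis).
    """

    n_H: float
    n_O: float
    n_N: float
    mu: float
    d: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_H, self.n_O, self.n_N) < 0:
            raise InvalidCompositionError(
                f"negative chemical index in {self!r}")
        if self.mu <= 0:
            raise InvalidCompositionError(
                f"chemical potential must be positive, got {self.mu}")
        if self.d <= 0:
            raise InvalidCompositionError(
                f"specific density must be positive, got {self.d}")

    @property
    def w(self) -> float:
        """Molar weight per C-mol, g/mol (derived from the indices)."""
        return (ATOMIC_WEIGHTS["C"]
                + self.n_H * ATOMIC_WEIGHTS["H"]
                + self.n_O * ATOMIC_WEIGHTS["O"]
                + self.n_N * ATOMIC_WEIGHTS["N"])

    def as_dict(self) -> dict:
        return {"n_H": self.n_H, "n_O": self.n_O, "n_N": self.n_N,
                "mu": self.mu, "d": self.d}


# Default generalised-compound table.  The indices for protein / lipid /
# carbohydrate are the conventional DEB values (carbohydrate is the glucose
# monomer CH2O); chemical potentials of the macronutrients are set from their
# combustion energies so that gross-energy and C-mol accounting agree.
# These are configuration defaults, overridable via ``build_compound_library``.
DEFAULT_COMBUSTION_KJ_PER_G = {"protein": 23.6, "fat": 39.5, "carb": 17.2}

_DEFAULTS = {
    "protein": dict(n_H=1.61, n_O=0.33, n_N=0.28, d=1.35),
    "fat": dict(n_H=1.92, n_O=0.12, n_N=0.0, d=0.92),
    "carb": dict(n_H=2.0, n_O=1.0, n_N=0.0, d=1.55),
    "reserve": dict(n_H=1.80, n_O=0.50, n_N=0.15, mu=550_000.0, d=0.30),
    "structure": dict(n_H=1.80, n_O=0.50, n_N=0.15, mu=500_000.0, d=0.20),
}


def build_compound_library(overrides: dict | None = None) -> dict[str, CompoundComposition]:
    """Build the macronutrient -> :class:`CompoundComposition` table.

    ``overrides`` maps a compound name (``protein``, ``fat``, ``carb``,
    ``reserve``, ``structure``) to a dict of fields to replace.  Molar weights
    are always derived from the indices, never supplied.
    """
    lib: dict[str, CompoundComposition] = {}
    for name, spec in _DEFAULTS.items():
        spec = dict(spec)
        if "mu" not in spec:
            # macronutrient: chemical potential from combustion energy
            w = (ATOMIC_WEIGHTS["C"] + spec["n_H"] + 16 * spec["n_O"]
                 + 14 * spec["n_N"])
            spec["mu"] = DEFAULT_COMBUSTION_KJ_PER_G[name] * 1e3 * w
        if overrides and name in overrides:
            spec.update(overrides[name])
        lib[name] = CompoundComposition(**spec)
    return lib


def default_library() -> dict[str, CompoundComposition]:
    return build_compound_library()


def library_to_yaml(lib: dict[str, CompoundComposition]) -> str:
    return yaml.safe_dump({k: v.as_dict() for k, v in lib.items()},
                          sort_keys=True)


def library_from_yaml(text: str) -> dict[str, CompoundComposition]:
    raw = yaml.safe_load(text)
    return {k: CompoundComposition(**v) for k, v in raw.items()}


@dataclass(frozen=True)
class DietSpec:
    """A feed in both proximate (mass) and C-mol terms.

    Mass fractions are on a dry-matter basis and must sum to 1; ``a_P`` is the
    C-mol fraction of the *ash-free* dry matter that is protein substrate.
    """

    frac_protein: float
    frac_fat: float
    frac_carb: float
    frac_ash: float
    moisture: float
    adc_protein: float
    adc_fat: float
    adc_carb: float
    a_P: float
    comp_XP: CompoundComposition
    comp_XnP: CompoundComposition
    w_X: float            # g ash-free dry feed per C-mol
    d_Xd: float           # specific density of dry food, g/cm^3
    d_Xw: float           # specific density of wet (as-fed) food, g/cm^3
    gross_energy: float   # kJ per g dry feed (ash included in the gram)
    adc_nP: float         # C-mol-weighted ADC of the non-protein substrate
    ash_per_cmol: float   # g ash ingested per C-mol ash-free dry feed
    name: str = "diet"

    @property
    def dry_to_wet(self) -> float:
        """Dry-to-wet mass conversion ratio d_Xd/d_Xw of the as-fed feed."""
        return self.d_Xd / self.d_Xw


def _require(cond: bool, err: type[Exception], msg: str) -> None:
    if not cond:
        raise err(msg)


def diet_from_proximate(
    fractions: dict,
    digestibilities: dict,
    library: dict[str, CompoundComposition] | None = None,
    densities: dict | None = None,
    moisture: float = 0.09,
    energy_coefficients: dict | None = None,
    name: str = "diet",
) -> DietSpec:
    """Build a :class:`DietSpec` from a proximate analysis.

    Parameters
    ----------
    fractions : dict
        Mass fractions of dry feed: keys ``protein``, ``fat``, ``carb``,
        ``ash``; must sum to 1.
    digestibilities : dict
        Apparent digestibility coefficients, keys ``protein``, ``fat``,
        ``carb``, each in [0, 1].
    library : dict, optional
        Compound library (default :func:`default_library`).
    densities : dict, optional
        ``{"dry": d_Xd, "wet": d_Xw}`` in g/cm^3 (defaults 0.65 / 0.71,
        a typical extruded pellet).
    moisture : float
        Moisture mass fraction of the as-fed feed (bookkeeping only).

    Ash is excluded from ``a_P``, ``w_X`` and all reserve dynamics, but its
    ingestion ratio is recorded so it can be traced to the faeces.
    """
    library = library or default_library()
    densities = densities or {"dry": 0.65, "wet": 0.71}

    fp = float(fractions.get("protein", 0.0))
    ff = float(fractions.get("fat", 0.0))
    fc = float(fractions.get("carb", 0.0))
    fa = float(fractions.get("ash", 0.0))
    for frac, label in [(fp, "protein"), (ff, "fat"), (fc, "carb"), (fa, "ash")]:
        _require(0.0 <= frac <= 1.0, InvalidCompositionError,
                 f"{label} fraction {frac} outside [0, 1]")
    total = fp + ff + fc + fa
    _require(abs(total - 1.0) <= 1e-9, InvalidCompositionError,
             f"dry-matter fractions must sum to 1, got {total}")
    _require(fp + ff + fc > 0.0, DegenerateDietError,
             "all-ash diet has no digestible organic matter")

    adc = {k: float(digestibilities[k]) for k in ("protein", "fat", "carb")}
    for k, v in adc.items():
        _require(0.0 <= v <= 1.0, InvalidCompositionError,
                 f"ADC of {k} must be in [0, 1], got {v}")

    prot, fat, carb = library["protein"], library["fat"], library["carb"]
    # C-mol of each macronutrient per g of dry feed
    c_prot = fp / prot.w
    c_fat = ff / fat.w
    c_carb = fc / carb.w
    c_tot = c_prot + c_fat + c_carb
    c_nP = c_fat + c_carb

    a_P = c_prot / c_tot
    w_X = (fp + ff + fc) / c_tot
    ash_per_cmol = fa / c_tot

    if c_nP > 0:
        wf, wc = c_fat / c_nP, c_carb / c_nP
        comp_XnP = CompoundComposition(
            n_H=wf * fat.n_H + wc * carb.n_H,
            n_O=wf * fat.n_O + wc * carb.n_O,
            n_N=wf * fat.n_N + wc * carb.n_N,
            mu=wf * fat.mu + wc * carb.mu,
            d=wf * fat.d + wc * carb.d,
        )
        adc_nP = wf * adc["fat"] + wc * adc["carb"]
    else:                     # pure-protein diet: placeholder, never consumed
        comp_XnP = replace(carb)
        adc_nP = adc["carb"]

    coeffs = energy_coefficients or DEFAULT_COMBUSTION_KJ_PER_G
    gross = fp * coeffs["protein"] + ff * coeffs["fat"] + fc * coeffs["carb"]

    return DietSpec(
        frac_protein=fp, frac_fat=ff, frac_carb=fc, frac_ash=fa,
        moisture=float(moisture),
        adc_protein=adc["protein"], adc_fat=adc["fat"], adc_carb=adc["carb"],
        a_P=a_P, comp_XP=prot, comp_XnP=comp_XnP, w_X=w_X,
        d_Xd=float(densities["dry"]), d_Xw=float(densities["wet"]),
        gross_energy=gross, adc_nP=adc_nP, ash_per_cmol=ash_per_cmol,
        name=name,
    )


def gross_energy_density(diet: DietSpec,
                         coefficients: dict | None = None) -> float:
    """Mass-weighted combustion energy of the dry feed, kJ/g (ash adds 0)."""
    coeffs = coefficients or DEFAULT_COMBUSTION_KJ_PER_G
    for k, v in coeffs.items():
        _require(v > 0, InvalidCompositionError,
                 f"combustion coefficient for {k} must be positive")
    return (diet.frac_protein * coeffs["protein"]
            + diet.frac_fat * coeffs["fat"]
            + diet.frac_carb * coeffs["carb"])


@dataclass(frozen=True)
class CouplingYields:
    """Stoichiometry of reserve synthesis from the two food substrates.

    ``q_P`` and ``q_nP`` are C-mol of protein / non-protein substrate consumed
    per C-mol reserve formed; ``y_PE`` is C-mol faeces produced per C-mol
    reserve.  ``comp_P`` is the faeces composition that closes the elemental
    balance of assimilation; ``co2_per_reserve`` is the assimilation CO2
    overhead (C-mol per C-mol reserve).
    """

    q_P: float
    q_nP: float
    y_PE: float
    comp_P: CompoundComposition
    co2_per_reserve: float
    ingested_P: float       # total ingested protein C-mol per reserve
    ingested_nP: float      # total ingested non-protein C-mol per reserve
    single_substrate: bool = False

    @property
    def total_food_per_reserve(self) -> float:
        """C-mol of food leaving the stomach per C-mol reserve formed:
        absorbed substrate plus the indigestible share egested as faeces,
        q_P + q_nP + y_PE (each carbon counted once)."""
        return self.q_P + self.q_nP + self.y_PE


def coupling_yields(diet: DietSpec,
                    reserve: CompoundComposition,
                    kappa_A: float = 0.8) -> CouplingYields:
    """Compute the coupling yields of reserve synthesis for a diet.

    ``q_P`` and ``q_nP`` are the *absorbed* substrate requirements of the
    synthesising unit; the indigestible share of the ingested food that must
    accompany them travels straight to the faeces as ``y_PE``.  The scheme
    closes the nitrogen and carbon balances of assimilation:

    * nitrogen — all reserve N comes from absorbed protein, so
      ``q_P = n_NE / n_N,protein``;
    * carbon — absorbed C is converted to reserve C with efficiency
      ``kappa_A`` (the remainder is respired as assimilation CO2), so
      ``q_P + q_nP = 1/kappa_A``;
    * faeces — each absorbed C-mol of a substrate drags along its
      indigestible companion ``(1-ADC)/ADC`` C-mol, so
      ``y_PE = (1-adc_P)/adc_P q_P + (1-adc_nP)/adc_nP q_nP``, with the
      faeces composition their C-mol-weighted mixture.

    With this closure the ammonia flux of assimilation is exactly zero, so the
    reported TAN carries only dissipation and growth terms while the
    four-element audit stays exact, and every ingested carbon is counted
    exactly once in ``q_P + q_nP + y_PE``.
    """
    _require(0.0 < kappa_A <= 1.0, InvalidCompositionError,
             f"kappa_A must be in (0, 1], got {kappa_A}")
    _require(diet.adc_protein > 0, InvalidCompositionError,
             "protein ADC must be positive to close the nitrogen balance")
    prot, xnp = diet.comp_XP, diet.comp_XnP

    q_P = reserve.n_N / prot.n_N
    q_nP = 1.0 / kappa_A - q_P
    _require(q_nP > 0, InvalidCompositionError,
             "reserve N demand exceeds the carbon budget; "
             "lower n_NE or raise kappa_A")
    adc_nP = diet.adc_nP if diet.adc_nP > 0 else 1.0

    # indigestible C-mol accompanying the absorbed substrate
    f_P = (1.0 - diet.adc_protein) / diet.adc_protein * q_P
    f_nP = (1.0 - adc_nP) / adc_nP * q_nP
    y_PE = f_P + f_nP
    if y_PE > 0:
        comp_P = CompoundComposition(
            n_H=(f_P * prot.n_H + f_nP * xnp.n_H) / y_PE,
            n_O=(f_P * prot.n_O + f_nP * xnp.n_O) / y_PE,
            n_N=(f_P * prot.n_N + f_nP * xnp.n_N) / y_PE,
            mu=(f_P * prot.mu + f_nP * xnp.mu) / y_PE,
            d=(f_P * prot.d + f_nP * xnp.d) / y_PE,
        )
    else:                                     # fully digestible feed
        comp_P = replace(prot)

    co2 = q_P + q_nP - 1.0                    # carbon surplus of assimilation
    single = diet.a_P in (0.0, 1.0)
    return CouplingYields(q_P=q_P, q_nP=q_nP, y_PE=y_PE, comp_P=comp_P,
                          co2_per_reserve=co2,
                          ingested_P=q_P / diet.adc_protein,
                          ingested_nP=q_nP / adc_nP,
                          single_substrate=single)
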