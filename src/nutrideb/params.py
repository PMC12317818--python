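"""Combined model parameter set: DEB core + digestion + compound library."""

from __future__ import annotations

from dataclasses import dataclass, field

from .deb_core import DEBCoreParams
from .digestion import DigestionParams
from .feed_chemistry import CompoundComposition, default_library

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Everything needed to simulate one fish.

    The surface-specific maximum assimilation rate appears twice — as power
    (``core.p_Am``, J/d/cm^2) and as a molar rate (``digestion.J_EAm_d``,
    mol/d/cm^2); they must agree through the chemical potential of reserve,
    ``p_Am = mu_E * J_EAm_d``, which is validated here.
    """

    core: DEBCoreParams
    digestion: DigestionParams
    library: dict[str, CompoundComposition] = field(default_factory=default_library)

    def __post_init__(self) -> None:
        expected = self.core.p_Am / self.core.mu_E
        if abs(self.digestion.J_EAm_d - expected) > 1e-9 * expected:
            raise ValueError(
                "inconsistent assimilation rates: p_Am/mu_E = "
                f"{expected:.6g} mol/d/cm^2 but J_EAm_d = "
                f"{self.digestion.J_EAm_d:.6g}")
        for name in ("reserve", "structure", "protein", "fat", "carb"):
            if name not in self.library:
                raise ValueError(f"compound library is missing '{name}'")
        res = self.library["reserve"]
        if abs(res.mu - self.core.mu_E) > 1e-6 * self.core.mu_E:
            raise ValueError("library reserve mu must equal core mu_E")
        if abs(res.w - self.core.w_Ed) > 1e-6 * self.core.w_Ed:
            raise ValueError("library reserve w must equal core w_Ed")

    @property
    def reserve(self) -> CompoundComposition:
        return self.library["reserve"]

    @property
    def structure(self) -> CompoundComposition:
        return self.library["structure"]
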