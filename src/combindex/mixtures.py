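"""Fixed mass-ratio mixture designs and dose bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MixtureDesign:
    """Two-agent mixture at a fixed mass ratio.

    ``mass_fractions`` must sum to 1; e.g. a 1:20 (w/w) extract-in-carrier
    loading is fractions (20/21, 1/21) for (carrier, extract).
    """

    component_ids: tuple[str, str]
    mass_fractions: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.component_ids) != 2 or len(self.mass_fractions) != 2:
            raise ValueError("a MixtureDesign has exactly two components")
        w1, w2 = self.mass_fractions
        if w1 <= 0 or w2 <= 0:
            raise ValueError("mass fractions must be strictly positive")
        if abs(w1 + w2 - 1.0) > 1e-12:
            raise ValueError(f"mass fractions must sum to 1, got {w1 + w2}")

    @classmethod
    def from_ratio(cls, carrier: str, extract: str, parts_carrier: float, parts_extract: float) -> "MixtureDesign":
        """E.g. ``from_ratio("H", "LFL", 20, 1)`` for a 1:20 (w/w) loading."""
        total = parts_carrier + parts_extract
        return cls((carrier, extract), (parts_carrier / total, parts_extract / total))

    def fraction(self, component: str) -> float:
        try:
            return self.mass_fractions[self.component_ids.index(component)]
        except ValueError:
            raise KeyError(
                f"unknown component {component!r}; design has {self.component_ids}"
            ) from None


def component_dose(total_mixture_dose: float, design: MixtureDesign, component: str) -> float:
    """Dose of one component delivered by a total-mixture dose.

    Converts total-mixture concentration to component-basis concentration:
    component dose = mass fraction × total dose.  With a 1:20 (w/w) loading
    the extract fraction is 1/21, so e.g. a total-mixture IC50 of
    10.59 mg/mL corresponds to 0.50 mg/mL on the extract basis.
    """
    return design.fraction(component) * total_mixture_dose
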