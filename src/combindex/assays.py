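"""Raw plate signals to effect metrics.

Covers the signal semantics of the four antioxidant assays and the growth
panel: percent inhibition for the radical-scavenging assays (DPPH, ABTS),
linear signal calibrations for the reducing-power assays (FRAP, CUPRAC),
Trolox-relative potency measures (EC at 1 mM Trolox, TEAC), percent bacterial
growth for the prebiotic panel, and the pH-differential anthocyanin content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class RejectedWellError(ValueError):
    """Raised when a well fails its physical precondition."""


@dataclass(frozen=True)
class RawWell:
    """One blank-corrected inhibition measurement.

    ``sample_signal`` / ``sample_blank`` are the absorbance of the sample
    with and without the chromogenic substrate; ``substrate_signal`` /
    ``substrate_blank`` are the uninhibited substrate and its solvent blank.
    """

    sample_signal: float
    sample_blank: float
    substrate_signal: float
    substrate_blank: float

    def __post_init__(self) -> None:
        for name in ("sample_signal", "sample_blank", "substrate_signal", "substrate_blank"):
            if not math.isfinite(getattr(self, name)):
                raise RejectedWellError(f"non-finite absorbance in {name!r}: {self!r}")


@dataclass(frozen=True)
class InhibitionObservation:
    """Inhibited/uninhibited fractions (percent) at one concentration."""

    concentration: float
    fi: float
    fu: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"negative concentration {self.concentration}")
        if abs(self.fi + self.fu - 100.0) > 1e-9:
            raise ValueError(f"fi + fu must equal 100, got {self.fi + self.fu}")


def inhibition_fraction(well: RawWell, concentration: float = 0.0) -> InhibitionObservation:
    """Percent inhibition of the substrate by the sample.

    fi = ((A0 − Ablank_0) − (As − Ablank_s)) / (A0 − Ablank_0) × 100,
    fu = 100 − fi.  The blank-corrected substrate signal must be positive;
    otherwise the well is rejected (a dead substrate well carries no signal
    to inhibit).
    """
    a0 = well.substrate_signal - well.substrate_blank
    if a0 <= 0:
        raise RejectedWellError(
            f"non-positive blank-corrected substrate signal ({a0:.4g}) in well {well!r}"
        )
    a_s = well.sample_signal - well.sample_blank
    fi = (a0 - a_s) / a0 * 100.0
    return InhibitionObservation(concentration=concentration, fi=fi, fu=100.0 - fi)


@dataclass(frozen=True)
class GrowthRecord:
    """OD600 of a supplemented culture against the unsupplemented control."""

    sample_signal: float
    sample_blank: float
    control_signal: float
    control_blank: float


def growth_percent(rec: GrowthRecord) -> float:
    """Bacterial growth as percent of the unsupplemented control.

    (As − Ablank_s)/(Ac − Ablank_c) × 100.  100% equals the control; above
    100 is growth promotion "(+)", below 100 inhibition "(−)".
    """
    denom = rec.control_signal - rec.control_blank
    if denom <= 0:
        raise RejectedWellError(f"non-positive control OD difference ({denom:.4g})")
    return (rec.sample_signal - rec.sample_blank) / denom * 100.0


def classify_growth(percent: float) -> str:
    """"promotion" for > 100, "inhibition" for < 100, "neutral" at 100."""
    if percent > 100.0:
        return "promotion"
    if percent < 100.0:
        return "inhibition"
    return "neutral"


@dataclass(frozen=True)
class AnthocyaninInput:
    """pH-differential absorbances plus the extraction bookkeeping.

    Defaults are the cyanidin-3-glucoside constants: molar absorptivity
    26,900 L·mol⁻¹·cm⁻¹ and molecular weight 449.2 g/mol.
    """

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float
    dilution_factor: float
    extract_volume: float  # litres
    sample_mass: float  # grams
    molar_absorptivity: float = 26900.0
    molecular_weight: float = 449.2
    pathlength: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be positive")
        if self.molar_absorptivity <= 0:
            raise ValueError("molar_absorptivity must be positive")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be ≥ 1")

    @property
    def delta_a(self) -> float:
        return (self.a520_ph1 - self.a700_ph1) - (self.a520_ph45 - self.a700_ph45)


def anthocyanin_content(inp: AnthocyaninInput) -> float:
    """Total anthocyanin content, mg cyanidin-3-glucoside per g dry weight.

    TAC = ΔA · MW · DF · V · 1000 / (ε · L · m) with V in litres and m in
    grams; multiply by 100 for per-100 g reporting.  A negative ΔA (possible
    pH-differential artifact) is returned as-is with a warning, not clamped.
    """
    delta = inp.delta_a
    if delta < 0:
        warnings.warn(
            f"negative pH-differential absorbance ΔA = {delta:.4g}; "
            "possible artifact, value returned unclamped",
            stacklevel=2,
        )
    return (
        delta
        * inp.molecular_weight
        * inp.dilution_factor
        * inp.extract_volume
        * 1000.0
        / (inp.molar_absorptivity * inp.pathlength * inp.sample_mass)
    )


@dataclass(frozen=True)
class CalibrationResults:
    """Linear signal-vs-concentration fit (Trolox or a phenolic standard)."""

    slope: float
    intercept: float
    r_squared: float
    concentration_unit: str
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")
        if not math.isfinite(self.slope):
            raise ValueError("non-finite calibration slope")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0,1]: {self.r_squared}")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def summary(self) -> str:
        return (
            f"Linear calibration ({self.concentration_unit}), n={self.n_points}\n"
            f"  slope     {self.slope:.6g}\n"
            f"  intercept {self.intercept:.6g}\n"
            f"  R²        {self.r_squared:.6f}"
        )


# kept as an alias for the domain-type name used in table outputs
CalibrationFit = CalibrationResults


class LinearCalibration:
    """Ordinary least-squares calibration model, signal on concentration."""

    def __init__(self, concentrations, signals, concentration_unit: str = "mg/mL"):
        conc = np.asarray(concentrations, dtype=float)
        sig = np.asarray(signals, dtype=float)
        if conc.shape != sig.shape:
            raise ValueError("concentrations and signals must have equal length")
        if conc.size < 3:
            raise ValueError(f"need ≥ 3 calibration points, got {conc.size}")
        if np.unique(conc).size < 2:
            raise ValueError("all calibration concentrations identical")
        self.concentrations = conc
        self.signals = sig
        self.concentration_unit = concentration_unit

    def fit(self) -> CalibrationResults:
        res = stats.linregress(self.concentrations, self.signals)
        return CalibrationResults(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            concentration_unit=self.concentration_unit,
            n_points=int(self.concentrations.size),
        )


def fit_linear_calibration(concentrations, signals, concentration_unit: str = "mg/mL") -> CalibrationResults:
    """OLS slope/intercept/R² of signal against concentration."""
    return LinearCalibration(concentrations, signals, concentration_unit).fit()


def effective_conc_at_trolox(
    sample_fit: CalibrationResults,
    trolox_fit: CalibrationResults,
    trolox_level: float = 1.0,
) -> float:
    """Sample concentration matching the signal of ``trolox_level`` mM Trolox.

    EC = (slope_T·level + intercept_T − intercept_S) / slope_S, in the
    sample calibration's concentration unit.  Lower EC = stronger reducer.
    """
    if sample_fit.slope <= 0:
        raise ValueError("sample calibration slope must be positive (no monotone response)")
    if trolox_fit.slope <= 0:
        raise ValueError("Trolox calibration slope must be positive")
    target = trolox_fit.predict(trolox_level)
    return (target - sample_fit.intercept) / sample_fit.slope


def teac(sample_fit: CalibrationResults, trolox_fit: CalibrationResults) -> float:
    """Trolox Equivalent Antioxidant Capacity: ratio of calibration slopes.

    mM Trolox equivalents per unit sample concentration; with equal
    intercepts, TEAC × EC(1 mM Trolox) = 1.
    """
    if trolox_fit.slope == 0:
        raise ValueError("Trolox calibration slope is zero")
    return sample_fit.slope / trolox_fit.slope
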