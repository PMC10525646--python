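"""Combination indices, isobolograms, and theoretical reference models.

The combination index (CI) follows dose addition (Loewe additivity): at a
chosen effect level, each component's dose inside the mixture is divided by
the dose of that component alone producing the same effect, and the two
ratios are summed,

    CI = (w1·Dmix)/D1 + (w2·Dmix)/D2

with w the mass fractions of the fixed-ratio design, Dmix the equi-effective
total-mixture dose and D1, D2 the solo equi-effective doses.  CI < 1 is
synergism, CI ≈ 1 additivity, CI > 1 antagonism; the band classification and
its integer codes follow the six-interval convention used for antioxidant
mixtures (0.5–0.7 strong synergism … CI > 2 strong antagonism).

Two effect-independence references complement the CI: the Webb fractional
product (Bliss independence) for the sigmoidal radical-scavenging assays and
plain signal addition for the linear reducing-power assays.  The Loewe
expected response solves the dose-addition equation for the effect of an
arbitrary dose pair and supports excess-over-Loewe grids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .doseresponse import DoseResponseDataset, MedianEffectModel, MedianEffectResults
from .mixtures import MixtureDesign

__all__ = [
    "CIResult",
    "IsobologramPoint",
    "FixedRatioSynergy",
    "SynergyResults",
    "classify_ci",
    "combination_index",
    "confidence_interval95",
    "isobologram",
    "webb_expected",
    "additive_signal_expected",
    "loewe_expected",
    "loewe_excess_grid",
]

# (lower, upper, label, code); half-open [lo, hi)
_CI_BANDS = (
    (0.0, 0.5, "very strong synergism", +2),
    (0.5, 0.7, "strong synergism", +2),
    (0.7, 0.9, "moderate synergism", +1),
    (0.9, 1.1, "nearly additive", 0),
    (1.1, 1.5, "moderate antagonism", -1),
    (1.5, 2.0, "moderate to strong antagonism", -2),
    (2.0, math.inf, "strong antagonism", -3),
)


def combination_index(
    solo1_equieffective: float,
    solo2_equieffective: float,
    mixture_equieffective_total: float,
    design: MixtureDesign,
) -> float:
    """Loewe combination index at one effect level.

    ``solo1_equieffective`` and ``solo2_equieffective`` are the doses of the
    two agents alone (each on its own concentration basis) that produce the
    effect; ``mixture_equieffective_total`` is the total-mixture dose
    producing the same effect.
    """
    if solo1_equieffective <= 0 or solo2_equieffective <= 0 or mixture_equieffective_total <= 0:
        raise ValueError("all equi-effective doses must be strictly positive")
    w1, w2 = design.mass_fractions
    return (
        w1 * mixture_equieffective_total / solo1_equieffective
        + w2 * mixture_equieffective_total / solo2_equieffective
    )


def classify_ci(ci: float) -> tuple[str, int]:
    """Band label and integer code for a combination index.

    Bands are half-open [lo, hi): 0.86 → moderate synergism (+1),
    1.54 → moderate to strong antagonism (−2), 1.0 → nearly additive (0).
    """
    if ci <= 0:
        raise ValueError(f"combination index must be positive, got {ci}")
    for lo, hi, label, code in _CI_BANDS:
        if lo <= ci < hi:
            return label, code
    raise AssertionError("unreachable: bands cover (0, inf)")  # pragma: no cover


def confidence_interval95(values) -> tuple[float, float, float]:
    """(mean, low, high) as mean ± 1.96·SD/√n over replicate estimates."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("no replicate estimates")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    half = 1.96 * sd / math.sqrt(n)
    return mean, mean - half, mean + half


@dataclass(frozen=True)
class CIResult:
    """Combination index at one effect level with spread and class."""

    effect_level: float
    ci: float
    ci_sd: float
    category: str
    category_code: int

    def __post_init__(self) -> None:
        if self.ci <= 0:
            raise ValueError("ci must be positive")
        label, code = classify_ci(self.ci)
        if (label, code) != (self.category, self.category_code):
            raise ValueError(
                f"category {self.category!r}/{self.category_code} inconsistent with ci={self.ci}"
            )

    @classmethod
    def from_estimates(
        cls, effect_level: float, ci_central: float, ci_replicates=None
    ) -> "CIResult":
        sd = 0.0
        if ci_replicates is not None and len(ci_replicates) > 1:
            sd = float(np.std(np.asarray(ci_replicates, dtype=float), ddof=1))
        label, code = classify_ci(ci_central)
        return cls(effect_level, ci_central, sd, label, code)


@dataclass(frozen=True)
class IsobologramPoint:
    """One point of an isobologram, with 95% bounds per coordinate."""

    axis1_dose: float
    axis2_dose: float
    kind: str  # "solo_intercept" | "mixture"
    x_ci95_low: float
    x_ci95_high: float
    y_ci95_low: float
    y_ci95_high: float


def isobologram(
    effect_level: float,
    solo1_estimates,
    solo2_estimates,
    mixture_total_estimates,
    design: MixtureDesign,
) -> list[IsobologramPoint]:
    """Isobologram points for one effect level.

    Each argument is the per-replicate equi-effective dose estimates of,
    respectively, agent 1 alone (x axis), agent 2 alone (y axis) and the
    total mixture.  Returns the two solo intercepts and the mixture point
    (w1·Dmix, w2·Dmix), each coordinate with mean ± 1.96·SD/√n bounds.
    The mixture lies on the straight line joining the intercepts exactly
    when CI = 1; below it for synergism, above for antagonism.
    """
    m1, lo1, hi1 = confidence_interval95(solo1_estimates)
    m2, lo2, hi2 = confidence_interval95(solo2_estimates)
    mm, lom, him = confidence_interval95(mixture_total_estimates)
    w1, w2 = design.mass_fractions
    return [
        IsobologramPoint(m1, 0.0, "solo_intercept", lo1, hi1, 0.0, 0.0),
        IsobologramPoint(0.0, m2, "solo_intercept", 0.0, 0.0, lo2, hi2),
        IsobologramPoint(
            w1 * mm, w2 * mm, "mixture", w1 * lom, w1 * him, w2 * lom, w2 * him
        ),
    ]


def webb_expected(fi1: float, fi2: float) -> float:
    """Expected percent inhibition of two non-interacting agents.

    Fractional product (Bliss independence):
    100·(1 − (1 − fi1/100)·(1 − fi2/100)).  Commutative; returns the other
    argument when one fi is 0; saturates at 100.
    """
    if fi1 > 100 or fi2 > 100:
        raise ValueError("inhibited fractions cannot exceed 100%")
    return 100.0 * (1.0 - (1.0 - fi1 / 100.0) * (1.0 - fi2 / 100.0))


def additive_signal_expected(signal1: float, signal2: float) -> float:
    """Additive theoretical signal for linear assays (FRAP/CUPRAC): the sum.

    A theoretical curve below the experimental mixture curve indicates
    synergism; above, antagonism.
    """
    if not (math.isfinite(signal1) and math.isfinite(signal2)):
        raise ValueError("signals must be finite")
    return signal1 + signal2


_F_EPS = 1e-6


def loewe_expected(
    dose1: float,
    dose2: float,
    fit1: MedianEffectResults,
    fit2: MedianEffectResults,
) -> float:
    """Effect (percent) of a dose pair under Loewe additivity.

    Solves d1/D1(f) + d2/D2(f) = 1 for f, with D_i(f) the solo
    equi-effective dose from each median-effect fit.  Single-agent margins
    reduce to the forward model.  The residual is strictly decreasing in f,
    so the root in (0, 100) is unique; if no sign change exists inside the
    bracket the nearer boundary is returned with a warning.
    """
    if dose1 < 0 or dose2 < 0 or dose1 + dose2 <= 0:
        raise ValueError("doses must be non-negative with a positive sum")
    if dose2 == 0:
        return fit1.predict_fi(dose1)
    if dose1 == 0:
        return fit2.predict_fi(dose2)

    def residual(f: float) -> float:
        return dose1 / fit1.ic_at(f) + dose2 / fit2.ic_at(f) - 1.0

    lo, hi = _F_EPS, 100.0 - _F_EPS
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo < 0:  # even a vanishing effect over-covers: effect below bracket
        warnings.warn("Loewe effect below bracket; boundary value returned", stacklevel=2)
        return lo
    if r_hi > 0:
        warnings.warn("Loewe effect above bracket; boundary value returned", stacklevel=2)
        return hi
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


def loewe_excess_grid(
    observed,
    doses1,
    doses2,
    fit1: MedianEffectResults,
    fit2: MedianEffectResults,
):
    """Observed minus Loewe-expected inhibition over a dose grid.

    ``observed`` has shape (len(doses1), len(doses2)); positive excess means
    synergism (more inhibition than dose addition predicts), negative
    antagonism.  A cell with both doses zero has expected effect 0.
    """
    obs = np.asarray(observed, dtype=float)
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    if obs.shape != (d1.size, d2.size):
        raise ValueError(
            f"observed shape {obs.shape} does not match grid ({d1.size}, {d2.size})"
        )
    expected = np.zeros_like(obs)
    for i, a in enumerate(d1):
        for j, b in enumerate(d2):
            expected[i, j] = 0.0 if (a == 0 and b == 0) else loewe_expected(a, b, fit1, fit2)
    return obs - expected


@dataclass(frozen=True)
class SynergyResults:
    """Fitted synergy analysis of one fixed-ratio mixture."""

    design: MixtureDesign
    fit1: MedianEffectResults
    fit2: MedianEffectResults
    fit_mix: MedianEffectResults
    ci_results: tuple[CIResult, ...]
    isobolograms: dict  # effect level -> list[IsobologramPoint]
    replicate_ci: dict  # effect level -> list of per-replicate CI estimates

    def ci_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect_level": r.effect_level,
                    "ci": r.ci,
                    "ci_sd": r.ci_sd,
                    "category": r.category,
                    "category_code": r.category_code,
                }
                for r in self.ci_results
            ]
        )

    def isobologram_table(self) -> pd.DataFrame:
        rows = []
        for level, points in self.isobolograms.items():
            for p in points:
                rows.append(
                    {
                        "effect_level": level,
                        "kind": p.kind,
                        "x": p.axis1_dose,
                        "y": p.axis2_dose,
                        "x_ci95_low": p.x_ci95_low,
                        "x_ci95_high": p.x_ci95_high,
                        "y_ci95_low": p.y_ci95_low,
                        "y_ci95_high": p.y_ci95_high,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ids = self.design.component_ids
        lines = [
            f"Fixed-ratio synergy: {ids[0]} + {ids[1]} "
            f"(mass fractions {self.design.mass_fractions[0]:.4g}/{self.design.mass_fractions[1]:.4g})"
        ]
        for r in self.ci_results:
            lines.append(
                f"  effect {r.effect_level:g}%: CI = {r.ci:.3f} ± {r.ci_sd:.3f} "
                f"→ {r.category} ({r.category_code:+d})"
            )
        return "\n".join(lines)


class FixedRatioSynergy:
    """Combination-index model for a two-agent fixed-ratio mixture.

    Built from three dose–response datasets — each agent alone (on its own
    concentration basis) and the mixture (total-mixture basis) — plus the
    mass-ratio design.  ``fit()`` pools replicates for the central CI at
    each effect level and refits per replicate for the SD and the 95%
    isobologram intervals.
    """

    def __init__(
        self,
        solo1: DoseResponseDataset,
        solo2: DoseResponseDataset,
        mixture: DoseResponseDataset,
        design: MixtureDesign,
        effect_levels=(50.0, 20.0),
    ):
        self.solo1 = solo1
        self.solo2 = solo2
        self.mixture = mixture
        self.design = design
        self.effect_levels = tuple(float(x) for x in effect_levels)
        for level in self.effect_levels:
            if not 0.0 < level < 100.0:
                raise ValueError(f"effect levels must be in (0,100), got {level}")

    def fit(self) -> SynergyResults:
        fit1 = MedianEffectModel(self.solo1).fit()
        fit2 = MedianEffectModel(self.solo2).fit()
        fit_mix = MedianEffectModel(self.mixture).fit()

        rep1 = MedianEffectModel(self.solo1).fit_replicates()
        rep2 = MedianEffectModel(self.solo2).fit_replicates()
        rep_mix = MedianEffectModel(self.mixture).fit_replicates()
        common = sorted(set(rep1) & set(rep2) & set(rep_mix))

        ci_results = []
        isobolograms = {}
        replicate_ci = {}
        for level in self.effect_levels:
            ci_central = combination_index(
                fit1.ic_at(level), fit2.ic_at(level), fit_mix.ic_at(level), self.design
            )
            reps = [
                combination_index(
                    rep1[r].ic_at(level),
                    rep2[r].ic_at(level),
                    rep_mix[r].ic_at(level),
                    self.design,
                )
                for r in common
                if rep1[r].usable and rep2[r].usable and rep_mix[r].usable
            ]
            ci_results.append(CIResult.from_estimates(level, ci_central, reps))
            replicate_ci[level] = reps
            if common:
                isobolograms[level] = isobologram(
                    level,
                    [rep1[r].ic_at(level) for r in common],
                    [rep2[r].ic_at(level) for r in common],
                    [rep_mix[r].ic_at(level) for r in common],
                    self.design,
                )
        return SynergyResults(
            design=self.design,
            fit1=fit1,
            fit2=fit2,
            fit_mix=fit_mix,
            ci_results=tuple(ci_results),
            isobolograms=isobolograms,
            replicate_ci=replicate_ci,
        )
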