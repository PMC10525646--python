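"""Median-effect dose–response modelling.

The sigmoidal inhibition curve is linearized by the median-effect
transformation

    log10(fi / fu) = m · log10(dose) + n

where fi and fu are the inhibited and uninhibited percent fractions
(fi + fu = 100), m the slope and n the intercept.  The fitted line inverts
in closed form to any inhibitory concentration:

    IC_x = 10^((log10(x / (100 − x)) − n) / m),   IC50 = 10^(−n / m).

Only observations with fi strictly inside (0, 100) enter the fit: the
transform is undefined at the boundaries, and pro-oxidant wells (fi < 0) or
saturated wells (fi ≥ 100) carry no dose–response information on this scale.
Excluded points are counted, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assays import InhibitionObservation

__all__ = [
    "DoseResponseDataset",
    "MedianEffectModel",
    "MedianEffectResults",
    "UnfittableDatasetError",
    "fit_median_effect",
    "ic_at",
    "predict_fi",
]


class UnfittableDatasetError(ValueError):
    """Too few usable points for the log-linear median-effect fit."""


@dataclass
class DoseResponseDataset:
    """Replicated inhibition observations for one agent in one assay.

    ``observations`` maps replicate index -> list of InhibitionObservation.
    """

    agent_id: str
    observations: dict[int, list[InhibitionObservation]]
    assay: str = ""

    def __post_init__(self) -> None:
        for obs_list in self.observations.values():
            for obs in obs_list:
                if obs.concentration <= 0:
                    raise ValueError(
                        f"{self.agent_id}: concentrations must be strictly positive, "
                        f"got {obs.concentration}"
                    )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, agent_id: str, assay: str = "") -> "DoseResponseDataset":
        """Build from a tidy frame with columns concentration, fi, replicate."""
        obs: dict[int, list[InhibitionObservation]] = {}
        for _, row in df.iterrows():
            rep = int(row.get("replicate", 0))
            obs.setdefault(rep, []).append(
                InhibitionObservation(
                    concentration=float(row["concentration"]),
                    fi=float(row["fi"]),
                    fu=100.0 - float(row["fi"]),
                )
            )
        return cls(agent_id=agent_id, observations=obs, assay=assay)

    def replicates(self) -> list[int]:
        return sorted(self.observations)

    def flat(self, replicate: int | None = None) -> list[InhibitionObservation]:
        if replicate is not None:
            return list(self.observations.get(replicate, []))
        return [o for rep in self.replicates() for o in self.observations[rep]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"replicate": rep, "concentration": o.concentration, "fi": o.fi, "fu": o.fu}
            for rep in self.replicates()
            for o in self.observations[rep]
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MedianEffectResults:
    """Fitted median-effect line and its diagnostics."""

    agent_id: str
    m: float
    n: float
    r_squared: float
    n_used: int
    n_excluded: int
    assay: str = ""

    @property
    def usable(self) -> bool:
        """m > 0: effect increases with dose, line invertible to ICx."""
        return self.m > 0

    @property
    def ic50(self) -> float:
        return self.ic_at(50.0)

    def ic_at(self, effect_percent: float) -> float:
        """Dose giving ``effect_percent`` inhibition (closed-form inversion)."""
        if not 0.0 < effect_percent < 100.0:
            raise ValueError(f"effect level must be in (0,100), got {effect_percent}")
        if not self.usable:
            raise ValueError(f"non-monotone fit for {self.agent_id!r} (m = {self.m:.4g} ≤ 0)")
        ratio = effect_percent / (100.0 - effect_percent)
        return 10.0 ** ((math.log10(ratio) - self.n) / self.m)

    def predict_fi(self, dose):
        """Percent inhibition at ``dose`` (scalar or array), forward model."""
        dose_arr = np.asarray(dose, dtype=float)
        if np.any(dose_arr <= 0):
            raise ValueError("dose must be strictly positive")
        if not self.usable:
            raise ValueError(f"non-monotone fit for {self.agent_id!r} (m = {self.m:.4g} ≤ 0)")
        r = 10.0 ** (self.m * np.log10(dose_arr) + self.n)
        out = 100.0 * r / (1.0 + r)
        return float(out) if np.isscalar(dose) or dose_arr.ndim == 0 else out

    def summary(self) -> str:
        lines = [
            f"Median-effect fit: {self.agent_id}" + (f" ({self.assay})" if self.assay else ""),
            f"  m (slope)     {self.m:.4f}",
            f"  n (intercept) {self.n:.4f}",
            f"  R²            {self.r_squared:.4f}",
            f"  points used   {self.n_used} (excluded {self.n_excluded})",
        ]
        if self.usable:
            lines.append(f"  IC50          {self.ic50:.4g}")
            lines.append(f"  IC20          {self.ic_at(20):.4g}")
        else:
            lines.append("  non-monotone fit (m ≤ 0): ICx unavailable")
        return "\n".join(lines)


class MedianEffectModel:
    """Least-squares median-effect model for one dose–response dataset."""

    def __init__(self, data: DoseResponseDataset):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, agent_id: str, assay: str = "") -> "MedianEffectModel":
        return cls(DoseResponseDataset.from_dataframe(df, agent_id, assay))

    def _fit_points(self, observations: list[InhibitionObservation]) -> MedianEffectResults:
        usable = [o for o in observations if 0.0 < o.fi < 100.0]
        excluded = len(observations) - len(usable)
        concs = np.array([o.concentration for o in usable])
        if len(usable) < 3 or np.unique(concs).size < 3:
            raise UnfittableDatasetError(
                f"{self.data.agent_id}: need ≥ 3 distinct concentrations with fi in (0,100); "
                f"{len(usable)} usable points ({excluded} excluded)"
            )
        x = np.log10(concs)
        y = np.log10(np.array([o.fi / o.fu for o in usable]))
        res = stats.linregress(x, y)
        r2 = float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 0.0
        return MedianEffectResults(
            agent_id=self.data.agent_id,
            m=float(res.slope),
            n=float(res.intercept),
            r_squared=r2,
            n_used=len(usable),
            n_excluded=excluded,
            assay=self.data.assay,
        )

    def fit(self) -> MedianEffectResults:
        """Pooled fit: all replicates in one regression."""
        return self._fit_points(self.data.flat())

    def fit_replicates(self) -> dict[int, MedianEffectResults]:
        """One fit per replicate; feeds SD-based uncertainty downstream."""
        return {rep: self._fit_points(self.data.flat(rep)) for rep in self.data.replicates()}


def fit_median_effect(data: DoseResponseDataset) -> MedianEffectResults:
    """Pooled median-effect fit of a dataset (functional convenience)."""
    return MedianEffectModel(data).fit()


def ic_at(fit: MedianEffectResults, effect_percent: float) -> float:
    return fit.ic_at(effect_percent)


def predict_fi(fit: MedianEffectResults, dose):
    return fit.predict_fi(dose)
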