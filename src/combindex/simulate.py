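"""Synthetic plate-reader data with known ground truth.

Every generator writes the same tidy well table the analysis reads, so the
whole pipeline can be exercised without laboratory data.  Single agents
follow the median-effect model exactly; fixed-ratio mixtures are built
either under Loewe dose addition at a chosen target combination index or
under Bliss (Webb) independence; calibrations are straight lines; growth
panels reproduce stated growth percentages.  Noise is additive Gaussian on
absorbance — plate readers err on signal — so effect-scale noise propagates
through the blank corrections the way a real assay's would.  A fixed seed
gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mixtures import MixtureDesign
from .synergy import webb_expected

__all__ = [
    "AgentTruth",
    "MixtureTruth",
    "NoiseSpec",
    "simulate_single_agent",
    "simulate_fixed_ratio_mixture",
    "simulate_calibration",
    "simulate_growth_panel",
    "simulate_interaction_study",
]

# physical plausibility window for a plate reader; signals at the detection
# ceiling (>3.5 AU) are unusable, so noise draws outside it are redrawn
_ABS_MIN, _ABS_MAX = 0.0, 3.5


@dataclass(frozen=True)
class AgentTruth:
    """Ground-truth median-effect parameters of one agent.

    Default substrate absorbance 0.70 AU is the ABTS working value
    (radical solution diluted to 0.700 ± 0.04 before reading).
    """

    m_true: float
    ic50_true: float
    substrate_absorbance: float = 0.70
    blank_level: float = 0.05

    def __post_init__(self) -> None:
        if self.m_true <= 0 or self.ic50_true <= 0:
            raise ValueError("m_true and ic50_true must be positive")
        if self.substrate_absorbance <= self.blank_level:
            raise ValueError("substrate absorbance must exceed the blank level")

    def fi(self, dose) -> np.ndarray:
        """True percent inhibition at a dose (median-effect forward model)."""
        r = (np.asarray(dose, dtype=float) / self.ic50_true) ** self.m_true
        return 100.0 * r / (1.0 + r)

    def ic_at(self, effect_percent: float) -> float:
        ratio = effect_percent / (100.0 - effect_percent)
        return self.ic50_true * ratio ** (1.0 / self.m_true)


@dataclass(frozen=True)
class MixtureTruth:
    """How the mixture's response is constructed from the margins."""

    design: MixtureDesign
    mode: str = "loewe"  # "loewe" | "bliss"
    target_ci: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("loewe", "bliss"):
            raise ValueError(f"mode must be 'loewe' or 'bliss', got {self.mode!r}")
        if self.target_ci <= 0:
            raise ValueError("target_ci must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian absorbance noise and the replicate count."""

    absorbance_sd: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorbance_sd < 0:
            raise ValueError("absorbance_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")


def _noisy(rng: np.random.Generator, value: float, sd: float) -> float:
    """One absorbance draw, redrawn while outside the plausible window."""
    if sd == 0:
        return float(min(max(value, _ABS_MIN), _ABS_MAX))
    for _ in range(1000):
        draw = value + rng.normal(0.0, sd)
        if _ABS_MIN <= draw <= _ABS_MAX:
            return float(draw)
    return float(min(max(value, _ABS_MIN), _ABS_MAX))


def _wells_from_fi(
    fi_by_dose,
    doses,
    noise: NoiseSpec,
    sample_id: str,
    assay: str,
    substrate_absorbance: float,
    blank_level: float,
    conc_unit: str,
    wavelength_nm: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    # noise enters on the sample signal only: As = (1 − fi/100)·(A0 − blank)
    # + blank + ε; substrate and blank wells carry their stated levels, so
    # effect-scale noise is what the blank correction propagates
    sd = noise.absorbance_sd
    net = substrate_absorbance - blank_level
    rows = []
    for rep in range(1, noise.replicates + 1):
        rows.append((assay, sample_id, "substrate", np.nan, conc_unit, rep,
                     substrate_absorbance, wavelength_nm))
        rows.append((assay, sample_id, "substrate_blank", np.nan, conc_unit, rep,
                     blank_level, wavelength_nm))
        for dose, fi in zip(doses, fi_by_dose):
            signal = (1.0 - fi / 100.0) * net + blank_level
            rows.append((assay, sample_id, "sample", dose, conc_unit, rep,
                         _noisy(rng, signal, sd), wavelength_nm))
            rows.append((assay, sample_id, "sample_blank", dose, conc_unit, rep,
                         blank_level, wavelength_nm))
    return pd.DataFrame(
        rows,
        columns=["assay", "sample_id", "role", "concentration", "conc_unit",
                 "replicate", "absorbance", "wavelength_nm"],
    )


def simulate_single_agent(
    truth: AgentTruth,
    doses,
    noise: NoiseSpec,
    sample_id: str = "agent",
    assay: str = "dpph",
    conc_unit: str = "mg/mL",
    wavelength_nm: float = 517.0,
) -> tuple[pd.DataFrame, dict]:
    """Wells for one agent's inhibition dose series, plus the truth record."""
    doses = list(doses)
    if not doses:
        raise ValueError("empty dose list")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be strictly positive")
    if len(set(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    rng = np.random.default_rng(noise.seed)
    fi = truth.fi(np.array(doses))
    wells = _wells_from_fi(
        fi, doses, noise, sample_id, assay,
        truth.substrate_absorbance, truth.blank_level, conc_unit, wavelength_nm, rng,
    )
    truth_record = {
        "sample_id": sample_id,
        "assay": assay,
        "m_true": truth.m_true,
        "ic50_true": truth.ic50_true,
        "substrate_absorbance": truth.substrate_absorbance,
        "blank_level": truth.blank_level,
        "doses": doses,
        "noise_sd": noise.absorbance_sd,
        "replicates": noise.replicates,
        "seed": noise.seed,
    }
    return wells, truth_record


def loewe_mixture_effect(
    total_dose: float,
    truth1: AgentTruth,
    truth2: AgentTruth,
    design: MixtureDesign,
    target_ci: float,
) -> float:
    """Effect f of a total mixture dose under the Loewe construction.

    The generative map is D(f) = target_ci / (w1/D1(f) + w2/D2(f)) with
    D_i(f) each agent's solo equi-effective dose; D(f) is strictly
    increasing, so the inverse f(D) is found by root bracketing.  By
    construction the full pipeline's CI equals target_ci at every effect
    level on noiseless data.
    """
    w1, w2 = design.mass_fractions

    def residual(f: float) -> float:
        return w1 / truth1.ic_at(f) + w2 / truth2.ic_at(f) - target_ci / total_dose

    lo, hi = 1e-9, 100.0 - 1e-9
    if residual(lo) < 0:
        return lo
    if residual(hi) > 0:
        return hi
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=300))


def simulate_fixed_ratio_mixture(
    truth1: AgentTruth,
    truth2: AgentTruth,
    mix: MixtureTruth,
    total_doses,
    noise: NoiseSpec,
    sample_id: str = "mixture",
    assay: str = "dpph",
    conc_unit: str = "mg/mL",
    wavelength_nm: float = 517.0,
) -> tuple[pd.DataFrame, dict]:
    """Wells for a fixed-ratio mixture dose series, plus the truth record.

    Loewe mode places the mixture's response so the combination index
    recovered by the analysis equals ``mix.target_ci``; Bliss mode sets each
    total dose's effect to the Webb fractional product of the margins.
    """
    total_doses = list(total_doses)
    if not total_doses:
        raise ValueError("empty dose list")
    if any(d <= 0 for d in total_doses):
        raise ValueError("doses must be strictly positive")
    w1, w2 = mix.design.mass_fractions
    if mix.mode == "loewe":
        fi = [
            loewe_mixture_effect(d, truth1, truth2, mix.design, mix.target_ci)
            for d in total_doses
        ]
    else:
        fi = [
            webb_expected(float(truth1.fi(w1 * d)), float(truth2.fi(w2 * d)))
            for d in total_doses
        ]
    rng = np.random.default_rng(noise.seed)
    wells = _wells_from_fi(
        fi, total_doses, noise, sample_id, assay,
        truth1.substrate_absorbance, truth1.blank_level, conc_unit, wavelength_nm, rng,
    )
    truth_record = {
        "sample_id": sample_id,
        "assay": assay,
        "mode": mix.mode,
        "target_ci": mix.target_ci,
        "component_ids": list(mix.design.component_ids),
        "mass_fractions": list(mix.design.mass_fractions),
        "agent1": {"m_true": truth1.m_true, "ic50_true": truth1.ic50_true},
        "agent2": {"m_true": truth2.m_true, "ic50_true": truth2.ic50_true},
        "total_doses": total_doses,
        "noise_sd": noise.absorbance_sd,
        "replicates": noise.replicates,
        "seed": noise.seed,
    }
    return wells, truth_record


def simulate_calibration(
    slope: float,
    intercept: float,
    levels,
    noise: NoiseSpec,
    sample_id: str = "trolox",
    assay: str = "frap",
    conc_unit: str = "mM",
    wavelength_nm: float = 593.0,
) -> tuple[pd.DataFrame, dict]:
    """Linear calibrant wells (e.g. Trolox 0.25–2 mM, or 50–450 µg/mL)."""
    levels = list(levels)
    if len(levels) < 3:
        raise ValueError(f"need ≥ 3 calibration levels, got {len(levels)}")
    rng = np.random.default_rng(noise.seed)
    rows = []
    for rep in range(1, noise.replicates + 1):
        for level in levels:
            signal = slope * level + intercept
            rows.append((assay, sample_id, "calibrant", level, conc_unit, rep,
                         _noisy(rng, signal, noise.absorbance_sd), wavelength_nm))
    wells = pd.DataFrame(
        rows,
        columns=["assay", "sample_id", "role", "concentration", "conc_unit",
                 "replicate", "absorbance", "wavelength_nm"],
    )
    truth_record = {
        "sample_id": sample_id,
        "assay": assay,
        "slope": slope,
        "intercept": intercept,
        "levels": levels,
        "noise_sd": noise.absorbance_sd,
        "replicates": noise.replicates,
        "seed": noise.seed,
    }
    return wells, truth_record


def simulate_growth_panel(
    true_growth_percents,
    control_od: float,
    noise: NoiseSpec,
    concentrations=None,
    sample_id: str = "sample",
    control_id: str = "C+",
    blank_level: float = 0.05,
    conc_unit: str = "mg/mL",
) -> tuple[pd.DataFrame, dict]:
    """OD600 growth panel around an unsupplemented control.

    ``control_od`` is the net (blank-corrected) control OD600 after
    incubation; each sample well's net OD is control_od × percent/100.  The
    default concentration ladder spans 1–45 mg/mL at five levels.
    """
    if control_od <= 0:
        raise ValueError("control_od must be positive")
    percents = list(true_growth_percents)
    if concentrations is None:
        concentrations = [45.0, 25.0, 10.0, 5.0, 1.0][: len(percents)]
    concentrations = list(concentrations)
    if len(concentrations) != len(percents):
        raise ValueError("one concentration per growth percent required")
    rng = np.random.default_rng(noise.seed)
    sd = noise.absorbance_sd
    rows = []
    for rep in range(1, noise.replicates + 1):
        rows.append(("growth", control_id, "control", np.nan, conc_unit, rep,
                     _noisy(rng, blank_level + control_od, sd), 600.0))
        rows.append(("growth", control_id, "control_blank", np.nan, conc_unit, rep,
                     _noisy(rng, blank_level, sd), 600.0))
        for conc, pct in zip(concentrations, percents):
            rows.append(("growth", sample_id, "sample", conc, conc_unit, rep,
                         _noisy(rng, blank_level + control_od * pct / 100.0, sd), 600.0))
            rows.append(("growth", sample_id, "sample_blank", conc, conc_unit, rep,
                         _noisy(rng, blank_level, sd), 600.0))
    wells = pd.DataFrame(
        rows,
        columns=["assay", "sample_id", "role", "concentration", "conc_unit",
                 "replicate", "absorbance", "wavelength_nm"],
    )
    truth_record = {
        "sample_id": sample_id,
        "control_id": control_id,
        "true_growth_percents": percents,
        "concentrations": concentrations,
        "control_od": control_od,
        "blank_level": blank_level,
        "noise_sd": sd,
        "replicates": noise.replicates,
        "seed": noise.seed,
    }
    return wells, truth_record


def simulate_interaction_study(
    seed: int = 0,
    target_ci: float = 1.0,
    noise_sd: float = 0.01,
    mode: str = "loewe",
    replicates: int = 3,
    carrier: AgentTruth | None = None,
    extract: AgentTruth | None = None,
    assay: str = "dpph",
):
    """One complete synergy study: carrier, extract, and 1:20 (w/w) mixture.

    Defaults mirror the antioxidant study design: the carrier (honey-like)
    is dosed 2–200 mg/mL, the extract 0.1–10 mg/mL (its IC50 near
    0.45 mg/mL), the mixture on the total-mixture basis 2–200 mg/mL, eight
    log-spaced doses each, three replicates.  Returns
    ``(datasets, design, truth)`` where ``datasets`` maps
    carrier/extract/mixture to DoseResponseDataset objects ready for the
    median-effect and combination-index models.
    """
    from .plate_io import inhibition_dataset

    if carrier is None:
        carrier = AgentTruth(m_true=1.5, ic50_true=50.0)
    if extract is None:
        extract = AgentTruth(m_true=1.5, ic50_true=0.45)
    design = MixtureDesign.from_ratio("carrier", "extract", 20, 1)
    mix = MixtureTruth(design, mode, target_ci)

    carrier_doses = list(np.geomspace(2.0, 200.0, 8))
    extract_doses = list(np.geomspace(0.1, 10.0, 8))
    total_doses = list(np.geomspace(2.0, 200.0, 8))

    w_c, t_c = simulate_single_agent(
        carrier, carrier_doses, NoiseSpec(noise_sd, replicates, seed * 3 + 1),
        sample_id="carrier", assay=assay)
    w_e, t_e = simulate_single_agent(
        extract, extract_doses, NoiseSpec(noise_sd, replicates, seed * 3 + 2),
        sample_id="extract", assay=assay)
    w_m, t_m = simulate_fixed_ratio_mixture(
        carrier, extract, mix, total_doses, NoiseSpec(noise_sd, replicates, seed * 3 + 3),
        sample_id="mixture", assay=assay)
    wells = pd.concat([w_c, w_e, w_m], ignore_index=True)
    datasets = {
        sid: inhibition_dataset(wells, sid, assay=assay)
        for sid in ("carrier", "extract", "mixture")
    }
    truth = {"carrier": t_c, "extract": t_e, "mixture": t_m, "wells": wells}
    return datasets, design, truth
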