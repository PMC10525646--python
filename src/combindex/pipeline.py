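"""End-to-end orchestration: plate CSV + run config → report bundle.

``run_synergy_analysis`` drives the whole interaction analysis for one
assay: median-effect fits and ICx for the sigmoidal assays (DPPH/ABTS), or
linear calibrations and EC at 1 mM Trolox for the reducing assays
(FRAP/CUPRAC); combination indices with replicate SD and classification;
isobologram coordinates with 95% intervals; and theoretical-vs-experimental
reference curves (Webb for sigmoidal, signal addition for linear).
``run_prebiotic_summary`` reduces an OD600 growth panel to percent-of-control
with promotion/inhibition flags.

Unreachable quantities become explicit NA rows, never silent omissions;
exclusions and extrapolations are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import plate_io
from .assays import (
    classify_growth,
    effective_conc_at_trolox,
    fit_linear_calibration,
    growth_percent,
    teac,
)
from .doseresponse import MedianEffectModel, UnfittableDatasetError
from .mixtures import MixtureDesign, component_dose
from .synergy import (
    CIResult,
    FixedRatioSynergy,
    classify_ci,
    combination_index,
    isobologram,
    webb_expected,
)

logger = logging.getLogger("combindex")

SIGMOIDAL_ASSAYS = {"dpph", "abts"}
LINEAR_ASSAYS = {"frap", "cuprac"}


class RunConfig(BaseModel):
    """Declarative description of one analysis run."""

    assay: str
    plate_csv: str
    sample1: str  # carrier (honey / GFSw), x axis of isobolograms
    sample2: str  # extract, y axis
    mixture: str
    mass_fractions: tuple[float, float] = (20.0 / 21.0, 1.0 / 21.0)
    effect_levels: tuple[float, ...] = (50.0, 20.0)
    replicate_policy: str = "pooled"  # "pooled" | "per_replicate"
    trolox_id: str = "trolox"  # calibrant id for the linear assays
    control_id: str = "C+"  # growth control id
    output_dir: str = "."
    seed: int = 0

    @field_validator("effect_levels")
    @classmethod
    def _levels_in_range(cls, v):
        for x in v:
            if not 0.0 < x < 100.0:
                raise ValueError(f"effect levels must be in (0,100), got {x}")
        return v

    @field_validator("replicate_policy")
    @classmethod
    def _policy_known(cls, v):
        if v not in ("pooled", "per_replicate"):
            raise ValueError(f"replicate_policy must be pooled|per_replicate, got {v!r}")
        return v

    @property
    def design(self) -> MixtureDesign:
        return MixtureDesign((self.sample1, self.sample2), tuple(self.mass_fractions))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """All tabular outputs of one synergy run, writable as CSVs."""

    fits: pd.DataFrame
    ci_table: pd.DataFrame
    ic_total_basis: pd.DataFrame
    ic_extract_basis: pd.DataFrame
    isobologram: pd.DataFrame
    theoretical_curves: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("fits", "ci_table", "ic_total_basis", "ic_extract_basis",
                     "isobologram", "theoretical_curves"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, lineterminator="\n", na_rep="NA")
            paths[name] = path
        return paths


def _fit_row(sample_id: str, assay: str, results, doses) -> dict:
    row = {
        "agent_id": sample_id,
        "assay": assay,
        "m": results.m,
        "n": results.n,
        "r_squared": results.r_squared,
        "n_used": results.n_used,
        "n_excluded": results.n_excluded,
    }
    if results.n_excluded:
        logger.info("%s/%s: excluded %d points with fi outside (0,100)",
                    sample_id, assay, results.n_excluded)
    for label, level in (("ic50", 50.0), ("ic20", 20.0)):
        if results.usable:
            icx = results.ic_at(level)
            row[label] = icx
            if doses is not None and not (min(doses) <= icx <= max(doses)):
                logger.warning("%s/%s: %s = %.4g extrapolates beyond tested doses [%g, %g]",
                               sample_id, assay, label, icx, min(doses), max(doses))
        else:
            row[label] = np.nan
            logger.warning("%s/%s: non-monotone fit, %s unavailable", sample_id, assay, label)
    return row


def _sigmoidal_bundle(df: pd.DataFrame, config: RunConfig) -> ReportBundle:
    design = config.design
    datasets = {
        sid: plate_io.inhibition_dataset(df, sid, assay=config.assay)
        for sid in (config.sample1, config.sample2, config.mixture)
    }
    fit_rows = []
    fits = {}
    for sid, data in datasets.items():
        doses = sorted({o.concentration for o in data.flat()})
        try:
            fits[sid] = MedianEffectModel(data).fit()
            fit_rows.append(_fit_row(sid, config.assay, fits[sid], doses))
        except UnfittableDatasetError as exc:
            logger.warning("%s: %s", sid, exc)
            fit_rows.append({"agent_id": sid, "assay": config.assay, "m": np.nan,
                             "n": np.nan, "r_squared": np.nan, "n_used": 0,
                             "n_excluded": len(data.flat()), "ic50": np.nan, "ic20": np.nan})
    fits_df = pd.DataFrame(fit_rows)

    model = FixedRatioSynergy(
        datasets[config.sample1], datasets[config.sample2], datasets[config.mixture],
        design, effect_levels=config.effect_levels,
    )
    try:
        results = model.fit()
    except UnfittableDatasetError as exc:
        logger.warning("synergy model unfittable: %s", exc)
        na = pd.DataFrame()
        return ReportBundle(fits_df, na, na, na, na, na)

    ci_rows = []
    for r in results.ci_results:
        ci = r.ci
        if config.replicate_policy == "per_replicate" and results.replicate_ci[r.effect_level]:
            ci = float(np.mean(results.replicate_ci[r.effect_level]))
            r = CIResult.from_estimates(r.effect_level, ci, results.replicate_ci[r.effect_level])
        ci_rows.append({
            "method": config.assay.upper(),
            "effect_level": r.effect_level,
            "ci": round(r.ci, 3),
            "ci_sd": round(r.ci_sd, 3),
            "category": r.category,
            "category_code": r.category_code,
        })
    ci_df = pd.DataFrame(ci_rows)

    total_rows, extract_rows = [], []
    for level in config.effect_levels:
        total = results.fit_mix.ic_at(level) if results.fit_mix.usable else np.nan
        total_rows.append({
            "sample_id": config.mixture, "assay": config.assay,
            "effect_level": level, "ic_total_mixture": np.round(total, 2),
        })
        extract = component_dose(total, design, config.sample2) if np.isfinite(total) else np.nan
        extract_rows.append({
            "sample_id": config.mixture, "assay": config.assay,
            "effect_level": level, "ic_extract_basis": np.round(extract, 2),
        })
    iso_df = results.isobologram_table()
    iso_df.insert(0, "method", config.assay.upper())

    # theoretical (Webb) vs experimental mixture response over the tested doses
    mix_df = datasets[config.mixture].to_dataframe()
    theo_rows = []
    w1, w2 = design.mass_fractions
    for dose, grp in mix_df.groupby("concentration"):
        row = {"total_dose": dose, "fi_experimental_mean": grp["fi"].mean(),
               "fi_experimental_sd": grp["fi"].std(ddof=1)}
        if fits.get(config.sample1) is not None and fits.get(config.sample2) is not None \
                and fits[config.sample1].usable and fits[config.sample2].usable:
            row["fi_webb_expected"] = webb_expected(
                fits[config.sample1].predict_fi(w1 * dose),
                fits[config.sample2].predict_fi(w2 * dose),
            )
        else:
            row["fi_webb_expected"] = np.nan
        theo_rows.append(row)
    theo_df = pd.DataFrame(theo_rows).sort_values("total_dose").reset_index(drop=True)

    return ReportBundle(fits_df, ci_df, pd.DataFrame(total_rows),
                        pd.DataFrame(extract_rows), iso_df, theo_df)


def _linear_signal_fits(df: pd.DataFrame, sample_id: str, assay: str, per_replicate: bool):
    """Blank-corrected signal vs concentration fits of a sample's wells."""
    samp = df[(df["sample_id"] == sample_id) & (df["assay"] == assay)
              & df["role"].isin(["sample", "sample_blank"])]
    if samp.empty:
        raise ValueError(f"no wells for {sample_id!r} in assay {assay!r}")
    out = {}
    groups = samp.groupby("replicate") if per_replicate else [(None, samp)]
    for rep, grp in groups:
        merged = grp.pivot_table(index=["concentration", "replicate"], columns="role",
                                 values="absorbance", aggfunc="mean").reset_index()
        signal = merged["sample"] - merged.get("sample_blank", 0.0)
        out[rep] = fit_linear_calibration(merged["concentration"], signal)
    return out


def _linear_bundle(df: pd.DataFrame, config: RunConfig) -> ReportBundle:
    design = config.design
    conc, sig = plate_io.calibration_points(df, config.trolox_id, assay=config.assay)
    trolox_fit = fit_linear_calibration(conc, sig, concentration_unit="mM")

    ids = (config.sample1, config.sample2, config.mixture)
    pooled = {sid: _linear_signal_fits(df, sid, config.assay, False)[None] for sid in ids}
    per_rep = {sid: _linear_signal_fits(df, sid, config.assay, True) for sid in ids}

    fit_rows = []
    for sid in ids:
        f = pooled[sid]
        fit_rows.append({
            "agent_id": sid, "assay": config.assay, "m": f.slope, "n": f.intercept,
            "r_squared": f.r_squared, "n_used": f.n_points, "n_excluded": 0,
            "ec_1mM_trolox": effective_conc_at_trolox(f, trolox_fit),
            "teac": teac(f, trolox_fit),
        })
    fits_df = pd.DataFrame(fit_rows)

    ec = {sid: effective_conc_at_trolox(pooled[sid], trolox_fit) for sid in ids}
    ci_central = combination_index(ec[config.sample1], ec[config.sample2],
                                   ec[config.mixture], design)
    common = sorted(set(per_rep[ids[0]]) & set(per_rep[ids[1]]) & set(per_rep[ids[2]]))
    rep_ci, rep_ec = [], {sid: [] for sid in ids}
    for r in common:
        ecs = {sid: effective_conc_at_trolox(per_rep[sid][r], trolox_fit) for sid in ids}
        rep_ci.append(combination_index(ecs[config.sample1], ecs[config.sample2],
                                        ecs[config.mixture], design))
        for sid in ids:
            rep_ec[sid].append(ecs[sid])
    if config.replicate_policy == "per_replicate" and rep_ci:
        ci_central = float(np.mean(rep_ci))
    label, code = classify_ci(ci_central)
    sd = float(np.std(rep_ci, ddof=1)) if len(rep_ci) > 1 else 0.0
    ci_df = pd.DataFrame([{
        "method": config.assay.upper(), "effect_level": "EC@1mM Trolox",
        "ci": round(ci_central, 3), "ci_sd": round(sd, 3),
        "category": label, "category_code": code,
    }])

    total_rows = [{"sample_id": config.mixture, "assay": config.assay,
                   "effect_level": "EC@1mM Trolox",
                   "ic_total_mixture": round(ec[config.mixture], 2)}]
    extract_rows = [{"sample_id": config.mixture, "assay": config.assay,
                     "effect_level": "EC@1mM Trolox",
                     "ic_extract_basis": round(component_dose(ec[config.mixture], design,
                                                              config.sample2), 2)}]

    points = isobologram(50.0, rep_ec[config.sample1] or [ec[config.sample1]],
                         rep_ec[config.sample2] or [ec[config.sample2]],
                         rep_ec[config.mixture] or [ec[config.mixture]], design)
    iso_rows = [{
        "method": config.assay.upper(), "effect_level": "EC@1mM Trolox", "kind": p.kind,
        "x": p.axis1_dose, "y": p.axis2_dose,
        "x_ci95_low": p.x_ci95_low, "x_ci95_high": p.x_ci95_high,
        "y_ci95_low": p.y_ci95_low, "y_ci95_high": p.y_ci95_high,
    } for p in points]

    # additive-signal theoretical curve vs the experimental mixture signal
    w1, w2 = design.mass_fractions
    mix_wells = df[(df["sample_id"] == config.mixture) & (df["assay"] == config.assay)
                   & df["role"].isin(["sample", "sample_blank"])]
    theo_rows = []
    for dose, grp in mix_wells.groupby("concentration"):
        exp_sig = (grp[grp["role"] == "sample"]["absorbance"].mean()
                   - grp[grp["role"] == "sample_blank"]["absorbance"].mean())
        theo = (pooled[config.sample1].predict(w1 * dose)
                + pooled[config.sample2].predict(w2 * dose))
        theo_rows.append({"total_dose": dose, "signal_experimental": exp_sig,
                          "signal_additive_expected": theo})
    theo_df = pd.DataFrame(theo_rows).sort_values("total_dose").reset_index(drop=True)

    return ReportBundle(fits_df, ci_df, pd.DataFrame(total_rows),
                        pd.DataFrame(extract_rows), pd.DataFrame(iso_rows), theo_df)


def run_synergy_analysis(config: RunConfig, write: bool = True) -> ReportBundle:
    """Full interaction analysis for one assay; optionally writes CSVs."""
    df = plate_io.read_plate_csv(config.plate_csv)
    assay = config.assay.lower()
    if assay in SIGMOIDAL_ASSAYS:
        sub = df[df["assay"] == assay]
        if sub[sub["role"] == "substrate"].empty:
            rows = df.index[df["assay"] == assay].tolist()
            raise ValueError(
                f"missing substrate control wells for inhibition assay {assay!r} "
                f"(rows with this assay: {rows[:10]}{'…' if len(rows) > 10 else ''})"
            )
        bundle = _sigmoidal_bundle(df, config)
    elif assay in LINEAR_ASSAYS:
        bundle = _linear_bundle(df, config)
    else:
        raise ValueError(f"unsupported assay for synergy analysis: {config.assay!r}")
    if write:
        bundle.write(config.output_dir)
    return bundle


def run_prebiotic_summary(config: RunConfig, sample_ids=None, write: bool = True) -> pd.DataFrame:
    """Percent-of-control growth with promotion/inhibition flags.

    One row per (sample, concentration): mean ± SD growth percent over
    replicates and a "(+)" / "(−)" flag for promotion vs inhibition.
    """
    df = plate_io.read_plate_csv(config.plate_csv)
    growth = df[df["assay"] == "growth"]
    if growth[growth["role"] == "control"].empty:
        raise ValueError(f"missing growth control wells (control_id {config.control_id!r})")
    if sample_ids is None:
        sample_ids = sorted(
            set(growth.loc[growth["role"] == "sample", "sample_id"]) - {config.control_id}
        )
    rows = []
    for sid in sample_ids:
        recs = plate_io.growth_records(growth, sid, control_id=config.control_id)
        by_conc: dict[float, list[float]] = {}
        for conc, _rep, rec in recs:
            by_conc.setdefault(conc, []).append(growth_percent(rec))
        for conc in sorted(by_conc, reverse=True):
            vals = np.array(by_conc[conc])
            mean = float(vals.mean())
            flag = {"promotion": "(+)", "inhibition": "(−)", "neutral": ""}[classify_growth(mean)]
            rows.append({
                "sample_id": sid, "concentration": conc,
                "growth_percent_mean": mean,
                "growth_percent_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size), "flag": flag,
            })
    report = pd.DataFrame(rows)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "growth_report.csv", index=False, lineterminator="\n", na_rep="NA")
    return report
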