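"""Reading and writing the tidy plate-reader CSV dialect.

One row per well: ``assay`` (dpph|abts|frap|cuprac|growth|tac), ``sample_id``,
``role`` (sample|sample_blank|substrate|substrate_blank|calibrant|control|
control_blank), ``concentration``, ``conc_unit``, ``replicate``,
``absorbance``, ``wavelength_nm``.  UTF-8, header required, decimal point.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assays import GrowthRecord, RawWell, inhibition_fraction
from .doseresponse import DoseResponseDataset

PLATE_COLUMNS = [
    "assay",
    "sample_id",
    "role",
    "concentration",
    "conc_unit",
    "replicate",
    "absorbance",
    "wavelength_nm",
]

_ROLES = {
    "sample",
    "sample_blank",
    "substrate",
    "substrate_blank",
    "calibrant",
    "control",
    "control_blank",
}


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path} missing columns: {missing}")
    bad = set(df["role"].unique()) - _ROLES
    if bad:
        raise ValueError(f"plate CSV {path} has unknown roles: {sorted(bad)}")
    return df


def write_plate_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, PLATE_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def _mean_absorbance(group: pd.DataFrame) -> float:
    return float(group["absorbance"].mean())


def inhibition_dataset(df: pd.DataFrame, sample_id: str, assay: str | None = None) -> DoseResponseDataset:
    """Blank-correct sample wells against the substrate and collect fi.

    Substrate and substrate-blank wells are matched by replicate; sample and
    sample-blank wells by (concentration, replicate).
    """
    sub = df[df["role"].isin(["substrate", "substrate_blank"])]
    if assay is not None:
        sub = sub[sub["assay"] == assay]
    if sub[sub["role"] == "substrate"].empty:
        raise ValueError(f"no substrate wells for assay {assay!r} in plate data")
    samp = df[(df["sample_id"] == sample_id) & df["role"].isin(["sample", "sample_blank"])]
    if assay is not None:
        samp = samp[samp["assay"] == assay]
    if samp.empty:
        raise ValueError(f"no sample wells for {sample_id!r}")
    assay_label = assay or str(samp["assay"].iloc[0])

    observations: dict[int, list] = {}
    for (conc, rep), grp in samp.groupby(["concentration", "replicate"]):
        s_rows = grp[grp["role"] == "sample"]
        b_rows = grp[grp["role"] == "sample_blank"]
        if s_rows.empty:
            continue
        sub_rep = sub[sub["replicate"] == rep]
        sub_sig = sub_rep[sub_rep["role"] == "substrate"]
        sub_blank = sub_rep[sub_rep["role"] == "substrate_blank"]
        well = RawWell(
            sample_signal=_mean_absorbance(s_rows),
            sample_blank=_mean_absorbance(b_rows) if not b_rows.empty else 0.0,
            substrate_signal=_mean_absorbance(sub_sig),
            substrate_blank=_mean_absorbance(sub_blank) if not sub_blank.empty else 0.0,
        )
        obs = inhibition_fraction(well, concentration=float(conc))
        observations.setdefault(int(rep), []).append(obs)
    return DoseResponseDataset(agent_id=sample_id, observations=observations, assay=assay_label)


def calibration_points(df: pd.DataFrame, sample_id: str, assay: str | None = None):
    """(concentrations, mean signals over replicates) of calibrant wells."""
    cal = df[(df["sample_id"] == sample_id) & (df["role"] == "calibrant")]
    if assay is not None:
        cal = cal[cal["assay"] == assay]
    if cal.empty:
        raise ValueError(f"no calibrant wells for {sample_id!r}")
    grouped = cal.groupby("concentration")["absorbance"].mean().sort_index()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


def growth_records(df: pd.DataFrame, sample_id: str, control_id: str = "C+"):
    """Per-(concentration, replicate) GrowthRecord list for one sample.

    Returns tuples (concentration, replicate, GrowthRecord); control wells
    are matched by replicate under ``control_id``.
    """
    ctrl = df[(df["sample_id"] == control_id) & df["role"].isin(["control", "control_blank"])]
    if ctrl[ctrl["role"] == "control"].empty:
        raise ValueError(f"no control wells under sample_id {control_id!r}")
    samp = df[(df["sample_id"] == sample_id) & df["role"].isin(["sample", "sample_blank"])]
    out = []
    for (conc, rep), grp in samp.groupby(["concentration", "replicate"]):
        s_rows = grp[grp["role"] == "sample"]
        if s_rows.empty:
            continue
        b_rows = grp[grp["role"] == "sample_blank"]
        c_rep = ctrl[ctrl["replicate"] == rep]
        c_sig = c_rep[c_rep["role"] == "control"]
        c_blank = c_rep[c_rep["role"] == "control_blank"]
        rec = GrowthRecord(
            sample_signal=_mean_absorbance(s_rows),
            sample_blank=_mean_absorbance(b_rows) if not b_rows.empty else 0.0,
            control_signal=_mean_absorbance(c_sig),
            control_blank=_mean_absorbance(c_blank) if not c_blank.empty else 0.0,
        )
        out.append((float(conc), int(rep), rec))
    return out
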