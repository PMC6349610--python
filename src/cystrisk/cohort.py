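"""Cohort schema, I/O and multistate outcome coding.

A cohort is a pandas DataFrame with one row per patient undergoing radical
cystectomy.  Times are integer days with day 0 the day of surgery; the
analysis horizon is 90 days (closed: events on day 90 count).  Outcome coding
maps each patient onto the three transitions of the multistate model:

    A  hospitalized -> discharged      (time 0 to discharge)
    B  hospitalized -> dead            (inpatient death)
    C  discharged   -> dead            (post-discharge death, delayed entry
                                        at the discharge day)

The hospitalized-phase outcomes (discharge, inpatient death, censored in
hospital) are mutually exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HORIZON = 90

SEX_LEVELS = ["male", "female"]
CCI_LEVELS = ["0", "1", "2plus"]
CT_LEVELS = ["cT2", "cT3", "cT4"]
VOLUME_LEVELS = ["low", "intermediate", "high"]
VITAL_LEVELS = ["dead", "alive"]
REGION_LEVELS = [
    "NewEngland_MidAtlantic",
    "SouthAtlantic",
    "EastNorthCentral",
    "EastSouthCentral_WestSouthCentral",
    "WestNorthCentral",
    "Mountain_Pacific",
]
RACE_LEVELS = ["white", "black", "hispanic", "other"]
FACILITY_TYPE_LEVELS = ["community", "comprehensive_community", "academic", "other"]

#: canonical column order for cohort files
COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "race",
    "cci",
    "ct_stage",
    "facility_volume",
    "region",
    "facility_type",
    "year_dx",
    "t_discharge",
    "t_last",
    "vital",
]

#: candidate predictors of the transition models, as indicator blocks.
#: A categorical block enters or leaves model selection as a unit.
COVARIATE_BLOCKS = {
    "age": ["age_c"],
    "sex": ["sex_male"],
    "cci": ["cci_1", "cci_2plus"],
    "ct_stage": ["ct_cT3", "ct_cT4"],
    "volume": ["vol_intermediate", "vol_high"],
}

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "race": RACE_LEVELS,
    "cci": CCI_LEVELS,
    "ct_stage": CT_LEVELS,
    "region": REGION_LEVELS,
    "facility_type": FACILITY_TYPE_LEVELS,
    "vital": VITAL_LEVELS,
}

#: columns that may be empty in a valid file (missing covariates are later
#: multiply imputed; t_discharge is empty when the patient was never
#: discharged within observation)
_OPTIONAL_VALUES = {"race", "facility_type", "facility_volume", "t_discharge",
                    "age", "sex", "cci", "ct_stage"}


class SchemaError(ValueError):
    """The file structure does not match the cohort schema."""


class CohortValidationError(ValueError):
    """One or more rows violate a hard invariant.

    Attributes
    ----------
    errors : list of (patient_id, message)
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"{pid}: {msg}" for pid, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


def validate_cohort(df: pd.DataFrame) -> list[tuple[str, str]]:
    """Check every row against the patient-record invariants.

    Returns a list of ``(patient_id, message)`` pairs, empty when the table
    is valid.  Missing values in optional fields are not errors.
    """
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    errors: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pd.isna(row["t_last"]):
            errors.append((pid, "t_last is mandatory"))
            continue
        if row["t_last"] < 0:
            errors.append((pid, f"t_last must be >= 0, got {row['t_last']}"))
        if pd.isna(row["vital"]):
            errors.append((pid, "vital is mandatory"))
        td = row["t_discharge"]
        if pd.notna(td):
            if td < 0:
                errors.append((pid, f"t_discharge must be >= 0, got {td}"))
            elif pd.notna(row["t_last"]) and td > row["t_last"]:
                errors.append(
                    (pid, f"t_discharge ({td:g}) > t_last ({row['t_last']:g}) "
                          "violates t_discharge <= t_last"))
        if pd.notna(row["age"]) and row["age"] < 18:
            errors.append((pid, f"age must be >= 18, got {row['age']}"))
        vol = row["facility_volume"]
        if pd.notna(vol) and vol < 0:
            errors.append((pid, f"facility_volume must be >= 0, got {vol}"))
        for col, levels in _CATEGORICAL_LEVELS.items():
            val = row[col]
            if pd.notna(val) and val not in levels:
                errors.append((pid, f"{col}={val!r} not in {levels}"))
    return errors


def _as_level_string(v):
    """Normalize a parsed categorical cell to its string level ("0", not
    "0.0": pandas may have read a numeric-looking column as float)."""
    if pd.isna(v) or (isinstance(v, str) and not v):
        return None
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("age", "facility_volume", "year_dx", "t_discharge", "t_last"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _CATEGORICAL_LEVELS:
        df[col] = df[col].map(_as_level_string)
    return df


def read_cohort(path, mapping: dict[str, str] | None = None,
                on_invalid: str = "raise") -> pd.DataFrame:
    """Read a delimited cohort file and validate it.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    mapping : dict, optional
        Maps file column names onto schema names, e.g. ``{"AGE": "age"}``.
        Unmapped columns must already carry schema names.
    on_invalid : {"raise", "drop"}
        Whether invalid rows abort the read or are dropped (the dropped-row
        diagnostics are attached to the returned frame as ``df.attrs["rejected"]``).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    if mapping:
        df = df.rename(columns=mapping)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    df = _coerce_types(df)
    errors = validate_cohort(df)
    if errors:
        if on_invalid == "raise":
            raise CohortValidationError(errors)
        bad_ids = {pid for pid, _ in errors}
        df = df[~df["patient_id"].isin(bad_ids)].reset_index(drop=True)
        df.attrs["rejected"] = errors
    return df[COLUMNS + [c for c in df.columns if c not in COLUMNS]]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in canonical column order (UTF-8 CSV, empty
    fields for missing values)."""
    df.to_csv(path, index=False, columns=COLUMNS)


def derive_volume_category(volume):
    """Categorize a facility's prior-year cystectomy count into the
    approximate-tertile groups <5, 5-14, >=15.

    Accepts a scalar or array; missing stays missing.
    """
    vol = np.asarray(volume, dtype=float)
    scalar = vol.ndim == 0
    vol = np.atleast_1d(vol)
    if np.any(vol[~np.isnan(vol)] < 0):
        raise ValueError("facility volume must be nonnegative")
    out = np.full(vol.shape, None, dtype=object)
    out[vol < 5] = "low"
    out[(vol >= 5) & (vol < 15)] = "intermediate"
    out[vol >= 15] = "high"
    out[np.isnan(vol)] = None
    return out[0] if scalar else pd.array(out)


def derive_outcomes(df: pd.DataFrame, horizon: int = HORIZON) -> pd.DataFrame:
    """Derive the three-transition outcome coding from raw times.

    Rules (day resolution; a death on the discharge day counts as inpatient):

    * inpatient death  iff vital=dead and (no discharge or t_last <= t_discharge)
    * post-discharge death  iff vital=dead and t_discharge < t_last
    * everything is administratively censored at the horizon; a transition-C
      row exists only for patients discharged within the horizon and with a
      positive post-discharge at-risk window.
    """
    out = df.copy()
    if "volume_cat" not in out.columns:
        out["volume_cat"] = derive_volume_category(out["facility_volume"])

    td = out["t_discharge"].to_numpy(dtype=float)
    tl = out["t_last"].to_numpy(dtype=float)
    dead = (out["vital"] == "dead").to_numpy()

    discharged = ~np.isnan(td)
    inpatient_death = dead & (~discharged | (tl <= np.where(np.isnan(td), np.inf, td)))
    postdis_death = dead & discharged & (td < tl)
    # a death on the discharge day counts as inpatient, not as a discharge
    discharge_event = discharged & ~inpatient_death

    # hospitalized-phase exit: discharge day, inpatient-death day, or censoring
    hosp_exit = np.where(inpatient_death, tl, np.where(discharge_event, td, tl))
    a_status = discharge_event & (hosp_exit <= horizon)
    b_status = inpatient_death & (hosp_exit <= horizon)
    over = hosp_exit > horizon
    hosp_exit = np.minimum(hosp_exit, horizon)
    a_status &= ~over
    b_status &= ~over

    out["event_A_time"] = hosp_exit
    out["event_A_status"] = a_status.astype(int)
    out["event_B_time"] = hosp_exit
    out["event_B_status"] = b_status.astype(int)

    # post-discharge phase, delayed entry at the discharge day
    has_c = a_status.copy()
    c_entry = np.where(has_c, td, np.nan)
    c_exit = np.where(postdis_death, tl, tl)
    c_exit = np.minimum(np.where(has_c, c_exit, np.nan), horizon)
    c_status = postdis_death & (tl <= horizon) & has_c
    # zero-length at-risk windows carry no information
    has_c &= np.where(np.isnan(c_exit), False, c_exit > c_entry)
    out["event_C_entry"] = np.where(has_c, c_entry, np.nan)
    out["event_C_time"] = np.where(has_c, c_exit, np.nan)
    out["event_C_status"] = np.where(has_c, c_status.astype(float), np.nan)
    return out


def death_by_horizon(df: pd.DataFrame, horizon: int = HORIZON) -> pd.Series:
    """Indicator of death within the horizon (any state)."""
    return (df["vital"] == "dead") & (df["t_last"] <= horizon)


def _pct(k, n):
    return round(100.0 * k / n, 1)


def cohort_summary(df: pd.DataFrame, horizon: int = HORIZON) -> dict:
    """Baseline-characteristics summary with observed horizon mortality.

    Returns a dict with ``overall`` mortality, per-stratum mortality by
    volume category and facility type (``deaths``, ``n``, ``pct``), counts
    and percentages for every categorical covariate and median (IQR) for the
    continuous ones.
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    coded = df if "volume_cat" in df.columns else derive_outcomes(df, horizon)
    died = death_by_horizon(coded, horizon)

    def strata(col):
        rows = {}
        for level, grp in coded.groupby(col, observed=True):
            d = int(died[grp.index].sum())
            rows[level] = {"deaths": d, "n": len(grp), "pct": _pct(d, len(grp))}
        return rows

    categorical = {}
    for col in ("sex", "race", "cci", "ct_stage", "volume_cat", "region",
                "facility_type"):
        counts = coded[col].value_counts(dropna=False)
        categorical[col] = {
            (lvl if pd.notna(lvl) else "missing"): {"n": int(c),
                                                    "pct": _pct(int(c), len(coded))}
            for lvl, c in counts.items()}

    continuous = {}
    for col in ("age", "t_discharge", "t_last"):
        vals = coded[col].dropna()
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            continuous[col] = {"median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "n": len(coded),
        "overall_mortality": {"deaths": int(died.sum()), "n": len(coded),
                              "pct": _pct(int(died.sum()), len(coded))},
        "mortality_by_volume": strata("volume_cat"),
        "mortality_by_facility_type": strata("facility_type"),
        "categorical": categorical,
        "continuous": continuous,
    }


def design_matrix(df: pd.DataFrame, blocks=None, age_center: float = 0.0) -> pd.DataFrame:
    """Build the numeric covariate matrix for the transition regressions.

    ``blocks`` selects covariate blocks (default all of COVARIATE_BLOCKS);
    age enters continuously per year, centered at ``age_center``; every other
    block is dummy-coded against its reference level (female sex, CCI 0,
    cT2, low volume), matching the reporting convention for hazard ratios.
    """
    blocks = list(COVARIATE_BLOCKS) if blocks is None else list(blocks)
    cols = {}
    for block in blocks:
        if block == "age":
            if df["age"].isna().any():
                raise ValueError("missing age; impute before building the design matrix")
            cols["age_c"] = df["age"].to_numpy(dtype=float) - age_center
        elif block == "sex":
            _check_complete(df, "sex")
            cols["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
        elif block == "cci":
            _check_complete(df, "cci")
            cols["cci_1"] = (df["cci"] == "1").to_numpy(dtype=float)
            cols["cci_2plus"] = (df["cci"] == "2plus").to_numpy(dtype=float)
        elif block == "ct_stage":
            _check_complete(df, "ct_stage")
            cols["ct_cT3"] = (df["ct_stage"] == "cT3").to_numpy(dtype=float)
            cols["ct_cT4"] = (df["ct_stage"] == "cT4").to_numpy(dtype=float)
        elif block == "volume":
            vc = df["volume_cat"] if "volume_cat" in df.columns else \
                pd.Series(derive_volume_category(df["facility_volume"]), index=df.index)
            if vc.isna().any():
                raise ValueError("missing volume_cat; impute before building the design matrix")
            cols["vol_intermediate"] = (vc == "intermediate").to_numpy(dtype=float)
            cols["vol_high"] = (vc == "high").to_numpy(dtype=float)
        else:
            raise KeyError(f"unknown covariate block {block!r}")
    return pd.DataFrame(cols, index=df.index)


def _check_complete(df, col):
    if df[col].isna().any():
        raise ValueError(f"missing {col}; impute before building the design matrix")
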