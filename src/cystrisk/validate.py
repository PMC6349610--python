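"""Internal-external cross-validation (IECV) and report tables.

The cohort is split by the six US geographic regions; each region in turn
is held out, the transition models are refit (with fold-internal
re-imputation when predictors are missing, so no held-out row influences
imputation or fitting) on the remaining five, and discrimination
(Harrell's C) and calibration (slope of the development linear predictor in
a validation Cox refit) are measured per transition in the held-out region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import REGION_LEVELS, derive_outcomes
from .hazards import TRANSITIONS, build_transition_dataset, fit_transition_models
from .impute import impute


@dataclass
class ValidationResult:
    held_out_region: str
    transition: str
    c_statistic: float
    calibration_slope: float
    n_validation: int
    n_events: int


@dataclass
class ValidationSummary:
    results: list[ValidationResult] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def ranges(self) -> dict:
        t = self.table().dropna(subset=["c_statistic", "calibration_slope"])
        return {
            "c_statistic": (float(t["c_statistic"].min()),
                            float(t["c_statistic"].max())),
            "calibration_slope": (float(t["calibration_slope"].min()),
                                  float(t["calibration_slope"].max())),
        }


def iecv_split(cohort: pd.DataFrame):
    """Six leave-one-region-out (train, test) partitions.

    Test sets are disjoint, cover the cohort, and each equals one region.
    """
    present = set(cohort["region"].dropna().unique())
    empty = [r for r in REGION_LEVELS if r not in present]
    if empty:
        raise ValueError(f"region(s) with zero patients: {empty}")
    unknown = present - set(REGION_LEVELS)
    if unknown:
        raise ValueError(f"unknown region label(s): {sorted(unknown)}")
    splits = []
    for region in REGION_LEVELS:
        test = cohort[cohort["region"] == region]
        train = cohort[cohort["region"] != region]
        splits.append((region, train, test))
    return splits


def c_statistic(lp, entry, time, status) -> float:
    """Harrell's concordance with delayed entry.

    A pair (i, j) is usable when i has the event at t_i, j is still at risk
    at t_i (entry_j < t_i <= t_j, censored if t_j == t_i), and the pair is
    concordant when the subject with the higher linear predictor has the
    earlier event; predictor ties count 1/2.
    """
    lp = np.asarray(lp, dtype=float)
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=bool)
    num = 0.0
    den = 0
    for i in np.where(status)[0]:
        ti = time[i]
        later = (entry < ti) & ((time > ti) | ((time == ti) & ~status))
        later[i] = False
        n_pairs = int(later.sum())
        if n_pairs == 0:
            continue
        den += n_pairs
        num += np.sum(lp[i] > lp[later]) + 0.5 * np.sum(lp[i] == lp[later])
    if den == 0:
        raise ValueError("no usable pairs for the concordance index")
    return float(num / den)


def calibration_slope(lp, entry, time, status, with_se: bool = False):
    """Slope of the development-model linear predictor refit as the sole
    covariate of a validation Cox model (1 = optimal), delayed entry
    honored.  With ``with_se`` returns (slope, standard error)."""
    lp = np.asarray(lp, dtype=float)
    if np.all(lp == lp[0]):
        raise ValueError("constant linear predictor: slope undefined")
    if not np.any(np.asarray(status, dtype=bool)):
        raise ValueError("no events: slope undefined")
    df = pd.DataFrame({"lp": lp, "entry": np.asarray(entry, dtype=float),
                       "time": np.asarray(time, dtype=float),
                       "status": np.asarray(status, dtype=int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="status", entry_col="entry")
    slope = float(cph.params_["lp"])
    if with_se:
        return slope, float(cph.standard_errors_["lp"])
    return slope


def _transition_metrics(model, test_coded: pd.DataFrame, transition: str):
    td = build_transition_dataset(test_coded, transition)
    lp = model.linear_predictor(td)
    entry = td["entry"].to_numpy()
    time = td["time"].to_numpy()
    status = td["status"].to_numpy()
    n_events = int(status.sum())
    if n_events == 0 or len(np.unique(lp)) == 1:
        return np.nan, np.nan, len(td), n_events
    return (c_statistic(lp, entry, time, status),
            calibration_slope(lp, entry, time, status), len(td), n_events)


def run_iecv(cohort: pd.DataFrame, m: int = 5, seed: int = 0,
             select: bool = True, age_center: float | None = None) -> ValidationSummary:
    """Leave-one-region-out validation of the full modelling pipeline.

    When predictors are missing, each training fold is re-imputed on its own
    (strict, leakage-free mode) and the held-out region is imputed
    separately; with complete data the fold is fit directly.  A held-out
    region with zero events for a transition yields NaN metrics for that
    cell rather than aborting.
    """
    raw = cohort
    if age_center is None:
        age_center = float(raw["age"].dropna().mean())
    has_missing = raw[["age", "sex", "cci", "ct_stage", "facility_volume"]].isna().any().any()
    summary = ValidationSummary()
    rng = np.random.default_rng(seed)
    for region, train, test in iecv_split(raw):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if has_missing:
            train_sets = impute(train.reset_index(drop=True), m=m,
                                seed=fold_seed).datasets
            test_coded = impute(test.reset_index(drop=True), m=1,
                                seed=fold_seed + 1).datasets[0]
        else:
            train_sets = [derive_outcomes(train.reset_index(drop=True))]
            test_coded = derive_outcomes(test.reset_index(drop=True))
        models = fit_transition_models(train_sets, select=select,
                                       age_center=age_center)
        for tr in TRANSITIONS:
            c, slope, n_val, n_ev = _transition_metrics(models[tr], test_coded, tr)
            summary.results.append(ValidationResult(region, tr, c, slope,
                                                    n_val, n_ev))
    return summary


# --- report tables ---------------------------------------------------------

def hazard_ratio_table(models: dict) -> pd.DataFrame:
    """Per-transition HR table (exp(beta) with 95% CI from pooled SE)."""
    if not models:
        raise ValueError("missing models artifact")
    return pd.concat([models[tr].hazard_ratios() for tr in sorted(models)],
                     ignore_index=True)


def strata_table(predictions: pd.DataFrame,
                 thresholds=(0.05, 0.10, 0.15)) -> pd.DataFrame:
    """Risk-strata counts/proportions from a predictions frame."""
    from .statemodel import stratify_risk

    if predictions is None or len(predictions) == 0:
        raise ValueError("empty predictions artifact")
    frac = stratify_risk(predictions["p_death_90"], thresholds)
    n = len(predictions)
    return pd.DataFrame([
        {"threshold": th, "n_above": int(round(f * n)), "n": n, "proportion": f}
        for th, f in frac.items()])


def patient_card_table(models: dict, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-profile prediction cards (mortality, days per state, QALD)."""
    from .statemodel import predict_profiles

    res = predict_profiles(models, profiles)
    return pd.concat([profiles.reset_index(drop=True),
                      res.reset_index(drop=True)], axis=1)


def validation_table(summary: ValidationSummary) -> pd.DataFrame:
    if not summary.results:
        raise ValueError("missing validation artifact")
    return summary.table()
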