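"""Cause-specific Cox models for the three state transitions.

Each transition (A discharge, B inpatient death, C post-discharge death) is
fit by Cox partial likelihood on the day timescale since cystectomy, with
Efron tie handling (day-resolution data are heavily tied) and delayed entry
for the post-discharge transition (subjects enter its risk set at their
discharge day).  The daily baseline hazard at the reference covariate
pattern (female, CCI 0, cT2, low volume, age at the centering constant) is
obtained by differencing the Breslow cumulative baseline on the integer-day
grid.  Covariate selection is backward stepwise on whole categorical blocks
using AIC; with multiply imputed data, selection runs on the first completed
dataset and the chosen model is refit on every imputation and pooled by
Rubin's rules (baseline hazards are averaged pointwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import COVARIATE_BLOCKS, HORIZON, design_matrix
from .impute import pool_rubin

TRANSITIONS = ("A", "B", "C")
_TRANSITION_NAMES = {"A": "discharge", "B": "inpatient_death",
                     "C": "postdischarge_death"}


@dataclass
class HazardModel:
    """One fitted (or pooled) transition model."""
    transition: str
    coef: dict[str, float]              # log hazard ratios
    se: dict[str, float]
    baseline_cumhaz: np.ndarray         # H0 at days 0..horizon
    daily_h0: np.ndarray                # increments for days 1..horizon
    age_center: float
    n: int = 0
    n_events: int = 0
    log_likelihood: float | None = None
    selected_blocks: list[str] = field(default_factory=list)

    def hazard_ratios(self) -> pd.DataFrame:
        """exp(beta) with normal-approximation 95% CI."""
        rows = []
        for c, b in self.coef.items():
            s = self.se.get(c, np.nan)
            rows.append({"transition": self.transition, "covariate": c,
                         "log_hr": b, "se": s, "hr": np.exp(b),
                         "ci_low": np.exp(b - 1.96 * s),
                         "ci_high": np.exp(b + 1.96 * s)})
        return pd.DataFrame(rows)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """x'beta for cohort-like rows (age centered at ``age_center``)."""
        blocks = [b for b, cols in COVARIATE_BLOCKS.items()
                  if any(c in self.coef for c in cols)]
        D = design_matrix(X, blocks=blocks, age_center=self.age_center)
        if not self.coef:
            return np.zeros(len(X))
        return sum(v * D[c].to_numpy() for c, v in self.coef.items())


def build_transition_dataset(coded: pd.DataFrame, transition: str) -> pd.DataFrame:
    """Extract (entry, time, status) plus covariates for one transition.

    A and B share the hospitalized-phase rows with complementary status;
    C contains only subjects discharged within the horizon, with delayed
    entry at the discharge day.
    """
    if transition in ("A", "B"):
        out = coded.copy()
        out["entry"] = 0.0
        out["time"] = coded[f"event_{transition}_time"].astype(float)
        out["status"] = coded[f"event_{transition}_status"].astype(int)
    elif transition == "C":
        mask = coded["event_C_time"].notna()
        if not mask.any():
            raise ValueError("no discharged subjects: transition C undefined")
        out = coded[mask].copy()
        out["entry"] = out["event_C_entry"].astype(float)
        out["time"] = out["event_C_time"].astype(float)
        out["status"] = out["event_C_status"].astype(int)
    else:
        raise ValueError(f"unknown transition {transition!r}")
    out.attrs["transition"] = transition
    return out


def cox_log_partial_likelihood(entry, time, status, lp, ties: str = "efron") -> float:
    """Log partial likelihood at a given linear predictor, honoring delayed
    entry (risk set at event time t = {entry < t <= time}).

    Used for the null-model AIC in backward selection and as a cross-check
    against the fitter; supports Efron and Breslow tie handling.
    """
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=bool)
    lp = np.asarray(lp, dtype=float)
    elp = np.exp(lp)
    ll = 0.0
    for t in np.unique(time[status]):
        dead = status & (time == t)
        at_risk = (entry < t) & (time >= t)
        d = int(dead.sum())
        s_risk = elp[at_risk].sum()
        s_dead = elp[dead].sum()
        ll += lp[dead].sum()
        if ties == "efron":
            for l in range(d):
                ll -= np.log(s_risk - (l / d) * s_dead)
        elif ties == "breslow":
            ll -= d * np.log(s_risk)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return float(ll)


def breslow_baseline(entry, time, status, lp, horizon: int = HORIZON):
    """Breslow cumulative baseline hazard at the reference pattern (lp = 0),
    returned as (H0 at days 0..horizon, daily increments for days 1..horizon)."""
    entry = np.asarray(entry, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=bool)
    elp = np.exp(np.asarray(lp, dtype=float))
    daily = np.zeros(horizon)
    for t in np.unique(time[status]):
        if t < 1 or t > horizon:
            continue
        d = int((status & (time == t)).sum())
        at_risk = (entry < t) & (time >= t)
        daily[int(t) - 1] += d / elp[at_risk].sum()
    cumhaz = np.concatenate([[0.0], np.cumsum(daily)])
    return cumhaz, daily


def fit_cox(dataset: pd.DataFrame, blocks=None, age_center: float | None = None,
            horizon: int = HORIZON) -> HazardModel:
    """Fit one transition's Cox model (Efron ties, delayed entry).

    ``dataset`` comes from :func:`build_transition_dataset`; ``blocks``
    names the covariate blocks to include (default: all candidates).  An
    empty block list gives the null model (baseline hazard only).
    """
    if dataset["status"].sum() < 1:
        raise ValueError("no events in transition dataset")
    blocks = list(COVARIATE_BLOCKS) if blocks is None else list(blocks)
    if age_center is None:
        age_center = float(dataset["age"].mean()) if "age" in blocks else 0.0
    transition = str(dataset.attrs.get("transition", ""))

    entry = dataset["entry"].to_numpy(dtype=float)
    time = dataset["time"].to_numpy(dtype=float)
    status = dataset["status"].to_numpy(dtype=int)

    if blocks:
        D = design_matrix(dataset, blocks=blocks, age_center=age_center)
        const = [c for c in D.columns if D[c].nunique() <= 1]
        if const:
            raise ValueError(f"covariate(s) {const} constant over the dataset")
        fit_df = D.copy()
        fit_df["entry"] = entry
        fit_df["time"] = time
        fit_df["status"] = status
        cph = CoxPHFitter()
        cph.fit(fit_df, duration_col="time", event_col="status",
                entry_col="entry", show_progress=False)
        coef = cph.params_.to_dict()
        se = cph.standard_errors_.to_dict()
        lp = D.to_numpy() @ cph.params_.to_numpy()
        ll = float(cph.log_likelihood_)
    else:
        coef, se = {}, {}
        lp = np.zeros(len(dataset))
        ll = cox_log_partial_likelihood(entry, time, status, lp)

    cumhaz, daily = breslow_baseline(entry, time, status, lp, horizon)
    return HazardModel(transition=transition, coef=coef, se=se,
                       baseline_cumhaz=cumhaz, daily_h0=daily,
                       age_center=age_center, n=len(dataset),
                       n_events=int(status.sum()), log_likelihood=ll,
                       selected_blocks=blocks)


def aic(model: HazardModel) -> float:
    """AIC = -2 log partial likelihood + 2 (number of coefficients)."""
    return -2.0 * model.log_likelihood + 2.0 * len(model.coef)


def backward_select_aic(dataset: pd.DataFrame, blocks=None,
                        age_center: float | None = None):
    """Backward stepwise selection on whole covariate blocks by AIC.

    Starting from the full model, repeatedly removes the single block whose
    removal most decreases AIC; stops when no removal improves.  Returns
    (selected blocks, selection trace).  Deterministic: ties are broken in
    favour of removal, in candidate order.
    """
    current = list(COVARIATE_BLOCKS) if blocks is None else list(blocks)
    if age_center is None:
        age_center = float(dataset["age"].mean())
    trace = []
    current_aic = aic(fit_cox(dataset, current, age_center))
    trace.append({"blocks": list(current), "aic": current_aic, "removed": None})
    while current:
        candidates = []
        for b in current:
            reduced = [x for x in current if x != b]
            candidates.append((aic(fit_cox(dataset, reduced, age_center)), b))
        best_aic, best_block = min(candidates, key=lambda c: (c[0],))
        if best_aic < current_aic:
            current = [x for x in current if x != best_block]
            current_aic = best_aic
            trace.append({"blocks": list(current), "aic": current_aic,
                          "removed": best_block})
        else:
            break
    return current, trace


def pool_models(models: list[HazardModel]) -> HazardModel:
    """Rubin-pool per-imputation fits of one transition.

    Coefficients and SEs pool via Rubin's rules; the cumulative baseline
    hazard is averaged pointwise on the daily grid (it is not a coefficient
    estimate), which preserves monotonicity.
    """
    if not models:
        raise ValueError("nothing to pool")
    keys = list(models[0].coef)
    for m in models[1:]:
        if list(m.coef) != keys:
            raise ValueError("imputations have mismatched covariate sets")
        if m.age_center != models[0].age_center:
            raise ValueError("imputations have mismatched age centering")
    coef, se = {}, {}
    for k in keys:
        pooled = pool_rubin([m.coef[k] for m in models],
                            [m.se[k] ** 2 for m in models])
        coef[k] = pooled.estimate
        se[k] = pooled.se
    cumhaz = np.mean([m.baseline_cumhaz for m in models], axis=0)
    return HazardModel(transition=models[0].transition, coef=coef, se=se,
                       baseline_cumhaz=cumhaz, daily_h0=np.diff(cumhaz),
                       age_center=models[0].age_center,
                       n=models[0].n, n_events=models[0].n_events,
                       selected_blocks=list(models[0].selected_blocks))


def fit_transition_models(datasets: list[pd.DataFrame], select: bool = True,
                          age_center: float | None = None,
                          horizon: int = HORIZON):
    """Full fitting pipeline over m completed (imputed) cohort tables.

    For each transition: backward-AIC selection on the first dataset, refit
    of the selected model on every dataset, Rubin pooling.  Returns
    ``{"A": HazardModel, "B": ..., "C": ...}``; each model also carries its
    selection in ``selected_blocks``.
    """
    if age_center is None:
        age_center = float(datasets[0]["age"].mean())
    models = {}
    for tr in TRANSITIONS:
        tds = [build_transition_dataset(d, tr) for d in datasets]
        if select:
            blocks, _ = backward_select_aic(tds[0], age_center=age_center)
        else:
            blocks = list(COVARIATE_BLOCKS)
        fits = [fit_cox(t, blocks, age_center, horizon) for t in tds]
        models[tr] = pool_models(fits) if len(fits) > 1 else fits[0]
    return models


# --- serialization ---------------------------------------------------------

def models_to_dict(models: dict) -> dict:
    out = {"age_center": models["A"].age_center, "transitions": {}}
    for tr, m in models.items():
        out["transitions"][tr] = {
            "name": _TRANSITION_NAMES.get(tr, tr),
            "coef": m.coef,
            "se": m.se,
            "baseline_cumhaz": [float(x) for x in m.baseline_cumhaz],
            "n": m.n, "n_events": m.n_events,
            "selected_blocks": m.selected_blocks,
        }
    return out


def models_from_dict(d: dict) -> dict:
    models = {}
    for tr, md in d["transitions"].items():
        cumhaz = np.asarray(md["baseline_cumhaz"], dtype=float)
        models[tr] = HazardModel(
            transition=tr, coef=dict(md["coef"]), se=dict(md["se"]),
            baseline_cumhaz=cumhaz, daily_h0=np.diff(cumhaz),
            age_center=float(d["age_center"]), n=int(md.get("n", 0)),
            n_events=int(md.get("n_events", 0)),
            selected_blocks=list(md.get("selected_blocks", [])))
    return models
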