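"""Multiple imputation of missing predictors and Rubin's-rules pooling.

Missing covariates are completed by chained equations: each incomplete
variable is regressed additively on all other predictors, the discharge and
death status indicators, and the Nelson-Aalen cumulative-hazard estimates
for discharge and death evaluated at the subject's own time (the standard
survival-aware imputation recipe).  Continuous variables use predictive mean
matching; categorical variables are drawn from multinomial logistic models.
Downstream coefficient estimates from the m completed datasets are combined
with Rubin's rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import HORIZON, death_by_horizon, derive_outcomes

#: predictor columns eligible for imputation
CONTINUOUS_PREDICTORS = ["age"]
CATEGORICAL_PREDICTORS = ["sex", "race", "cci", "ct_stage", "volume_cat",
                          "facility_type"]


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus provenance."""
    m: int
    datasets: list[pd.DataFrame]
    seed: int
    model_spec: dict = field(default_factory=dict)


@dataclass
class PooledEstimate:
    """A coefficient pooled across imputations by Rubin's rules."""
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total_var)


def _nelson_aalen_at_own_time(time, status):
    """NA cumulative-hazard estimate Sum d_i/n_i over event times <= t,
    evaluated at each subject's own time."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=bool)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    event_times, d = np.unique(time[status], return_counts=True)
    # n at risk just before each event time (everyone with time >= t_i)
    n_at_risk = len(time) - np.searchsorted(t_sorted, event_times, side="left")
    increments = d / n_at_risk
    cumhaz = np.concatenate([[0.0], np.cumsum(increments)])
    idx = np.searchsorted(event_times, time, side="right")
    return cumhaz[idx]


def nelson_aalen_auxiliaries(coded: pd.DataFrame) -> pd.DataFrame:
    """Two auxiliary columns for imputation models: the NA cumulative hazard
    of discharge and of death (any cause, horizon-censored), each evaluated
    at the subject's own event or censoring time."""
    time_d = coded["event_A_time"].to_numpy(dtype=float)
    status_d = coded["event_A_status"].to_numpy(dtype=bool)
    died = death_by_horizon(coded).to_numpy()
    time_m = np.minimum(coded["t_last"].to_numpy(dtype=float), HORIZON)
    return pd.DataFrame({
        "na_discharge": _nelson_aalen_at_own_time(time_d, status_d),
        "na_death": _nelson_aalen_at_own_time(time_m, died),
    }, index=coded.index)


def _encode_predictors(df: pd.DataFrame, cols) -> np.ndarray:
    """Dummy-encode a mixed predictor frame into a float design array."""
    parts = []
    for c in cols:
        v = df[c]
        if v.dtype.kind in "if":
            parts.append(v.to_numpy(dtype=float)[:, None])
        else:
            levels = sorted(x for x in v.dropna().unique())
            parts.append(np.column_stack([(v == lv).to_numpy(dtype=float)
                                          for lv in levels[1:]]) if len(levels) > 1
                         else np.zeros((len(df), 0)))
    return np.hstack(parts) if parts else np.zeros((len(df), 0))


def _impute_continuous_pmm(y, X, miss, rng, k=5):
    """Predictive mean matching: OLS on observed rows, then each missing
    value borrows the observed outcome of one of the k nearest predicted
    neighbours."""
    obs = ~miss
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
    pred_all = np.column_stack([np.ones(len(y)), X]) @ beta
    pred_obs = pred_all[obs]
    y_obs = y[obs]
    out = y.copy()
    for i in np.where(miss)[0]:
        d = np.abs(pred_obs - pred_all[i])
        donors = np.argpartition(d, min(k, len(d) - 1))[:k]
        out[i] = y_obs[rng.choice(donors)]
    return out


def _impute_categorical(y: pd.Series, X, miss, rng):
    """Multinomial logistic draw for the missing categories."""
    obs = ~miss
    y_obs = y[obs]
    levels = sorted(y_obs.unique())
    if len(levels) == 1:
        out = y.copy()
        out[miss] = levels[0]
        return out
    clf = LogisticRegression(max_iter=200)
    clf.fit(X[obs], y_obs)
    proba = clf.predict_proba(X[miss])
    cum = proba.cumsum(axis=1)
    u = rng.random(len(proba))
    picks = (u[:, None] < cum).argmax(axis=1)
    out = y.copy()
    out[miss] = np.asarray(clf.classes_)[picks]
    return out


def impute(cohort: pd.DataFrame, m: int = 20, seed: int = 0,
           model_spec: dict | None = None, sweeps: int = 5) -> ImputationSet:
    """Chained-equations multiple imputation of missing predictors.

    ``cohort`` may be raw or outcome-coded; outcome and status columns are
    never altered and always feed the imputation models (as status
    indicators plus Nelson-Aalen auxiliaries).  Deterministic given seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    coded = cohort if "event_A_status" in cohort.columns else derive_outcomes(cohort)
    aux = nelson_aalen_auxiliaries(coded)

    candidates = [c for c in CONTINUOUS_PREDICTORS + CATEGORICAL_PREDICTORS
                  if c in coded.columns]
    incomplete = [c for c in candidates if coded[c].isna().any()]
    for c in incomplete:
        if coded[c].isna().all():
            raise ValueError(f"variable {c!r} is 100% missing and cannot be imputed")

    spec = {
        "predictors": candidates,
        "auxiliaries": ["event_A_status", "death_by_horizon",
                        "na_discharge", "na_death"],
        "incomplete": incomplete,
        "method": "pmm+multinomial chained equations",
    }
    if model_spec:
        spec.update(model_spec)

    if not incomplete:
        return ImputationSet(m, [coded.copy() for _ in range(m)], seed, spec)

    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=m)
    extra = pd.DataFrame({
        "event_A_status": coded["event_A_status"].astype(float),
        "death_by_horizon": death_by_horizon(coded).astype(float),
        "na_discharge": aux["na_discharge"],
        "na_death": aux["na_death"],
    }, index=coded.index)

    datasets = []
    for s in child_seeds:
        rng = np.random.default_rng(int(s))
        work = coded.copy()
        # initial fill: random draws from the observed marginal
        for c in incomplete:
            miss = work[c].isna()
            pool = work.loc[~miss, c].to_numpy()
            work.loc[miss, c] = rng.choice(pool, size=int(miss.sum()))
        for _ in range(sweeps):
            for c in incomplete:
                miss = coded[c].isna().to_numpy()
                others = [p for p in candidates if p != c]
                X = np.hstack([_encode_predictors(work, others),
                               extra.to_numpy(dtype=float)])
                if c in CONTINUOUS_PREDICTORS:
                    y = work[c].to_numpy(dtype=float)
                    work[c] = _impute_continuous_pmm(y, X, miss, rng)
                else:
                    work[c] = _impute_categorical(work[c], X, miss, rng)
        datasets.append(work)
    return ImputationSet(m, datasets, seed, spec)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Rubin's rules for a scalar estimand across m imputations.

    pooled = mean(estimates); total variance = within + (1 + 1/m) * between,
    with Rubin's degrees of freedom (infinite when between-variance is 0).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate to pool")
    if est.shape != var.shape:
        raise ValueError("estimates and variances differ in length")
    m = est.size
    q = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    if between > 0 and m > 1:
        ratio = within / ((1.0 + 1.0 / m) * between)
        df = math.inf if ratio > 1e150 else (m - 1) * (1.0 + ratio) ** 2
    else:
        df = math.inf
    return PooledEstimate(q, within, between, total, df)
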