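"""Synthetic radical-cystectomy cohorts with known multistate ground truth.

The generator draws covariates from the marginal distributions of a large
US registry cohort of muscle-invasive bladder cancer patients treated with
cystectomy (median length of stay 8 days, ~69 y mean age, ~77% male) and
simulates event histories from a known three-transition hazard model whose
log hazard ratios are the published multivariable estimates for discharge,
inpatient death and post-discharge death.  Because the registry itself is
not public, this generator provides the ground truth against which
parameter recovery and end-to-end predictions are tested.

The simulation mechanism is the exact discrete-time analogue of the
prediction engine: on each day a hospitalized subject exits with probability
``1 - exp(-(hA + hB))`` (cause split proportional to the hazards) and a
discharged subject dies with probability ``1 - exp(-hC)``.  Baseline daily
hazards are piecewise functions calibrated numerically so that the simulated
cohort reproduces the published anchors (median LOS 8 d with IQR 7-12;
overall 90-day mortality 7.6%); the calibrated values are frozen in
:data:`DEFAULT_BASELINES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import (CCI_LEVELS, CT_LEVELS, FACILITY_TYPE_LEVELS, HORIZON,
                     RACE_LEVELS, REGION_LEVELS, derive_volume_category,
                     design_matrix)
from .statemodel import run_trace

#: Published multivariable hazard ratios (ground truth), as natural logs.
#: Keys are design-matrix columns; absent keys mean the covariate has no
#: effect on that transition (it was not selected in the published model).
TRUE_LOG_HR = {
    "A": {  # discharge
        "age_c": math.log(0.991),
        "sex_male": math.log(1.054),
        "cci_1": math.log(0.933),
        "cci_2plus": math.log(0.918),
        "ct_cT3": math.log(0.954),
        "ct_cT4": math.log(0.922),
        "vol_intermediate": math.log(0.997),
        "vol_high": math.log(1.116),
    },
    "B": {  # inpatient death
        "age_c": math.log(1.044),
        "cci_1": math.log(1.453),
        "cci_2plus": math.log(2.192),
        "vol_intermediate": math.log(0.892),
        "vol_high": math.log(0.639),
    },
    "C": {  # post-discharge death
        "age_c": math.log(1.060),
        "cci_1": math.log(1.533),
        "cci_2plus": math.log(1.696),
        "ct_cT3": math.log(1.507),
        "ct_cT4": math.log(1.892),
    },
}

#: age (years) at which the baseline hazards apply; age enters the linear
#: predictors centered at this value
TRUTH_AGE_CENTER = 69.0


@dataclass
class BaselineHazards:
    """Piecewise daily baseline hazards of the generator truth.

    Discharge (A) uses the discrete hazard of a two-component log-normal
    length-of-stay mixture (a short-stay bulk plus a complicated-course
    tail), scaled by ``scale_a``.  Inpatient death (B) is constant to
    ``b_knot`` days then decays; post-discharge death (C) is constant to
    ``c_knot`` days then decays.  ``scale_a``, ``b0`` and ``c0`` are
    calibrated (see :func:`calibrate_baselines`) so the default cohort hits
    the published marginal anchors.
    """
    los_mix_weight: float = 0.67
    los_mu1: float = math.log(7.2)
    los_sigma1: float = 0.16
    los_mu2: float = math.log(16.5)
    los_sigma2: float = 0.55
    scale_a: float = 1.0
    b0: float = 3.0e-4
    b_knot: int = 21
    b_decay: float = 0.5
    c0: float = 8.0e-4
    c_knot: int = 45
    c_decay: float = 0.6
    max_daily_hazard: float = 3.0

    def _los_cdf(self, t):
        w = self.los_mix_weight
        return (w * stats.norm.cdf((np.log(np.maximum(t, 1e-12)) - self.los_mu1) / self.los_sigma1)
                + (1 - w) * stats.norm.cdf((np.log(np.maximum(t, 1e-12)) - self.los_mu2) / self.los_sigma2))

    def daily(self, n_days: int = HORIZON):
        """Baseline hazards for days 1..n_days as three float arrays."""
        t = np.arange(1, n_days + 1, dtype=float)
        F = self._los_cdf(t)
        F_prev = self._los_cdf(t - 1)
        q = np.clip((F - F_prev) / np.maximum(1.0 - F_prev, 1e-12), 0.0, 0.999)
        h_a = np.minimum(self.scale_a * -np.log1p(-q), self.max_daily_hazard)
        h_b = np.where(t <= self.b_knot, self.b0, self.b0 * self.b_decay)
        h_c = np.where(t <= self.c_knot, self.c0, self.c0 * self.c_decay)
        return h_a, h_b, h_c


@dataclass
class TruthModel:
    """Generator-side transition model: daily baseline hazards plus the true
    log hazard ratios, mirroring the structure of a fitted model."""
    baselines: BaselineHazards
    log_hr: dict = field(default_factory=lambda: {k: dict(v) for k, v in TRUE_LOG_HR.items()})
    age_center: float = TRUTH_AGE_CENTER

    def transition_models(self, n_days: int = HORIZON):
        """View the truth as three HazardModel-like objects usable by the
        prediction engine (keys "A", "B", "C")."""
        h_a, h_b, h_c = self.baselines.daily(n_days)
        return {
            "A": _TruthTransition(h_a, self.log_hr["A"], self.age_center),
            "B": _TruthTransition(h_b, self.log_hr["B"], self.age_center),
            "C": _TruthTransition(h_c, self.log_hr["C"], self.age_center),
        }


@dataclass
class _TruthTransition:
    daily_h0: np.ndarray
    coef: dict
    age_center: float


@dataclass
class TabulatedBaselines:
    """Baseline hazards given directly as daily arrays (e.g. taken from a
    fitted model), extended by holding the last value."""
    h_a: np.ndarray
    h_b: np.ndarray
    h_c: np.ndarray

    def daily(self, n_days: int = HORIZON):
        def ext(h):
            h = np.asarray(h, dtype=float)
            if len(h) >= n_days:
                return h[:n_days]
            return np.concatenate([h, np.full(n_days - len(h), h[-1])])
        return ext(self.h_a), ext(self.h_b), ext(self.h_c)


def truth_from_models(models: dict) -> TruthModel:
    """Wrap fitted transition models as a generator truth, so cohorts can be
    simulated from a fitted model (e.g. for calibration self-consistency)."""
    return TruthModel(
        baselines=TabulatedBaselines(models["A"].daily_h0, models["B"].daily_h0,
                                     models["C"].daily_h0),
        log_hr={tr: dict(models[tr].coef) for tr in ("A", "B", "C")},
        age_center=models["A"].age_center)


#: Default covariate marginals (probabilities per level; age is a truncated
#: normal in years).  Volume counts are drawn within the category so that
#: the derived tertile categories have the published shares.
DEFAULT_MARGINALS = {
    "age": {"mean": 69.0, "sd": 10.4, "low": 30, "high": 95},
    "sex": {"male": 0.77, "female": 0.23},
    "race": {"white": 0.90, "black": 0.05, "hispanic": 0.02, "other": 0.03},
    "cci": {"0": 0.69, "1": 0.24, "2plus": 0.07},
    "ct_stage": {"cT2": 0.816, "cT3": 0.124, "cT4": 0.060},
    "volume_cat": {"low": 0.2414, "intermediate": 0.3744, "high": 0.3842},
    "region": {r: 1.0 / 6.0 for r in REGION_LEVELS},
    "facility_type": {"community": 0.060, "comprehensive_community": 0.440,
                      "academic": 0.495, "other": 0.005},
    "year_dx": {str(y): 0.1 for y in range(2003, 2013)},
}


@dataclass
class GeneratorConfig:
    n: int = 10000
    seed: int = 0
    marginals: dict = field(default_factory=lambda: {k: dict(v) if isinstance(v, dict) else v
                                                     for k, v in DEFAULT_MARGINALS.items()})
    truth: TruthModel | None = None
    #: per-column missingness: {"volume_cat": {"rate": 0.08, "mechanism": "MCAR"}}
    missingness: dict = field(default_factory=dict)
    followup: int = 365

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.truth is None:
            self.truth = TruthModel(baselines=default_baselines())
        for col, spec in self.missingness.items():
            rate = spec.get("rate", 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {col} outside [0, 1]")
        for name, dist in self.marginals.items():
            if name == "age":
                continue
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"marginals for {name} sum to {total}, not 1")


def _draw_categorical(rng, levels, probs, n):
    return rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))


def draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate table (independently across variables)."""
    m = config.marginals
    n = config.n
    a = m["age"]
    z = stats.truncnorm.rvs((a["low"] - a["mean"]) / a["sd"],
                            (a["high"] - a["mean"]) / a["sd"],
                            loc=a["mean"], scale=a["sd"], size=n,
                            random_state=rng)
    age = np.round(z).astype(int)

    vol_cat = _draw_categorical(rng, list(m["volume_cat"]), list(m["volume_cat"].values()), n)
    # a plausible count within each tertile bin
    counts = np.empty(n, dtype=int)
    low = vol_cat == "low"
    mid = vol_cat == "intermediate"
    high = vol_cat == "high"
    counts[low] = rng.integers(1, 5, size=low.sum())
    counts[mid] = rng.integers(5, 15, size=mid.sum())
    counts[high] = 15 + np.floor(rng.exponential(12.0, size=high.sum())).astype(int)

    df = pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "age": age,
        "sex": _draw_categorical(rng, list(m["sex"]), list(m["sex"].values()), n),
        "race": _draw_categorical(rng, list(m["race"]), list(m["race"].values()), n),
        "cci": _draw_categorical(rng, list(m["cci"]), list(m["cci"].values()), n),
        "ct_stage": _draw_categorical(rng, list(m["ct_stage"]), list(m["ct_stage"].values()), n),
        "facility_volume": counts,
        "region": _draw_categorical(rng, list(m["region"]), list(m["region"].values()), n),
        "facility_type": _draw_categorical(rng, list(m["facility_type"]),
                                           list(m["facility_type"].values()), n),
        "year_dx": _draw_categorical(rng, [int(y) for y in m["year_dx"]],
                                     list(m["year_dx"].values()), n).astype(int),
    })
    df["volume_cat"] = derive_volume_category(df["facility_volume"])
    return df


def _linear_predictors(df: pd.DataFrame, truth: TruthModel):
    lps = {}
    for key, coef in truth.log_hr.items():
        D = design_matrix(df, age_center=truth.age_center)
        lps[key] = sum(c * D[col].to_numpy() for col, c in coef.items())
    return lps


def simulate_events(df: pd.DataFrame, truth: TruthModel, followup: int,
                    rng: np.random.Generator):
    """Simulate (t_discharge, t_death) for each row of ``df`` by the daily
    Bernoulli mechanism; hazards beyond the last tabulated day hold their
    final value.  Returns float arrays (NaN = event did not occur)."""
    n = len(df)
    lp = _linear_predictors(df, truth)
    ea, eb, ec = np.exp(lp["A"]), np.exp(lp["B"]), np.exp(lp["C"])
    h0a, h0b, h0c = truth.baselines.daily(HORIZON)

    state = np.zeros(n, dtype=int)  # 0 hosp, 1 disc, 2 dead
    t_discharge = np.full(n, np.nan)
    t_death = np.full(n, np.nan)
    for t in range(1, followup + 1):
        i = min(t, HORIZON) - 1
        u_exit = rng.random(n)
        u_cause = rng.random(n)
        u_pd = rng.random(n)

        hosp = state == 0
        if hosp.any():
            ha = h0a[i] * ea
            hb = h0b[i] * eb
            total = ha + hb
            p_exit = -np.expm1(-total)
            exits = hosp & (u_exit < p_exit)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_a = np.where(total > 0, ha / np.where(total > 0, total, 1.0), 0.0)
            to_disc = exits & (u_cause < frac_a)
            to_dead = exits & ~to_disc
            t_discharge[to_disc] = t
            state[to_disc] = 1
            t_death[to_dead] = t
            state[to_dead] = 2

        disc = state == 1
        if disc.any():
            pc = -np.expm1(-h0c[i] * ec)
            dies = disc & (u_pd < pc) & (np.where(np.isnan(t_discharge), -1, t_discharge) < t)
            t_death[dies] = t
            state[dies] = 2
    return t_discharge, t_death


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a full synthetic cohort table (deterministic given seed)."""
    rng = np.random.default_rng(config.seed)
    df = draw_covariates(config, rng)
    t_discharge, t_death = simulate_events(df, config.truth, config.followup, rng)
    dead = ~np.isnan(t_death)
    df["t_discharge"] = t_discharge
    df["t_last"] = np.where(dead, t_death, float(config.followup))
    df["vital"] = np.where(dead, "dead", "alive")
    df = df.drop(columns=["volume_cat"])
    if config.missingness:
        df = inject_missingness(df, config.missingness, rng)
    return df


_MISSABLE = {"age", "sex", "race", "cci", "ct_stage", "facility_volume",
             "volume_cat", "facility_type"}


def inject_missingness(df: pd.DataFrame, spec: dict,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Blank covariate values according to per-column missingness specs.

    ``spec`` maps column -> {"rate": float, "mechanism": "MCAR" | "MAR_age"}.
    Under MAR_age the missingness probability increases linearly with age
    around the configured rate.  Outcome and status columns are never
    blanked; "volume_cat" is an alias for the underlying count column.
    """
    out = df.copy()
    for col, s in spec.items():
        target = "facility_volume" if col == "volume_cat" else col
        if target not in _MISSABLE:
            raise ValueError(f"cannot inject missingness into column {col!r}")
        rate = float(s.get("rate", 0.0))
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {col} outside [0, 1]")
        mechanism = s.get("mechanism", "MCAR")
        if mechanism == "MCAR":
            p = np.full(len(out), rate)
        elif mechanism == "MAR_age":
            age = out["age"].to_numpy(dtype=float)
            p = np.clip(rate * (1.0 + (age - np.nanmean(age)) / 30.0), 0.0, 1.0)
        else:
            raise ValueError(f"unknown missingness mechanism {mechanism!r}")
        mask = rng.random(len(out)) < p
        if mask.any():
            out[target] = out[target].mask(mask)
    return out


def true_risk(profiles: pd.DataFrame, truth: TruthModel,
              horizon: int = HORIZON) -> np.ndarray:
    """Exact horizon death probability under the truth model, by the same
    occupancy recursion as the prediction engine but on the generator's
    hazards.  ``profiles`` is a cohort-like frame of covariates."""
    from .statemodel import profile_hazards

    models = truth.transition_models(horizon)
    h_a, h_b, h_c = profile_hazards(models, profiles)
    trace = run_trace(h_a, h_b, h_c, horizon=horizon)
    if trace.ndim == 2:
        trace = trace[None]
    return trace[:, -1, 2]


def microsimulate_trace(h_a, h_b, h_c, n: int, seed: int) -> np.ndarray:
    """Monte Carlo estimate of the occupancy trace for one hazard profile by
    independent per-subject daily Bernoulli simulation (the test oracle for
    the deterministic recursion).

    Returns occupancy proportions with the same shape/meaning as
    :func:`cystrisk.statemodel.run_trace` for a single profile.
    """
    rng = np.random.default_rng(seed)
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    h_c = np.asarray(h_c, dtype=float)
    T = len(h_a)
    state = np.zeros(n, dtype=int)
    occ = np.zeros((T + 1, 3))
    occ[0] = [1.0, 0.0, 0.0]
    for t in range(1, T + 1):
        u_exit = rng.random(n)
        u_cause = rng.random(n)
        u_pd = rng.random(n)
        hosp = state == 0
        total = h_a[t - 1] + h_b[t - 1]
        p_exit = -math.expm1(-total)
        frac_a = h_a[t - 1] / total if total > 0 else 0.0
        exits = hosp & (u_exit < p_exit)
        to_disc = exits & (u_cause < frac_a)
        state[to_disc] = 1
        state[exits & ~to_disc] = 2
        disc = state == 1
        # subjects discharged this very cycle are not yet at post-discharge risk
        disc_at_risk = disc & ~to_disc
        p_c = -math.expm1(-h_c[t - 1])
        state[disc_at_risk & (u_pd < p_c)] = 2
        for s in range(3):
            occ[t, s] = np.mean(state == s)
    return occ


# ---------------------------------------------------------------------------
# baseline-hazard calibration


def _population_anchors(baselines: BaselineHazards, n_profiles: int = 40000,
                        seed: int = 12345):
    """Analytic cohort-average anchors under a given baseline spec: LOS CDF
    over days 1..90 among the discharged, plus inpatient and post-discharge
    death probabilities by day 90 (averaged over a covariate sample)."""
    truth = TruthModel(baselines=baselines)
    cfg = GeneratorConfig(n=n_profiles, seed=seed, truth=truth)
    rng = np.random.default_rng(seed)
    df = draw_covariates(cfg, rng)
    lp = _linear_predictors(df, truth)
    h0a, h0b, h0c = baselines.daily(HORIZON)
    h_a = h0a[None, :] * np.exp(lp["A"])[:, None]
    h_b = h0b[None, :] * np.exp(lp["B"])[:, None]
    h_c = h0c[None, :] * np.exp(lp["C"])[:, None]

    # hospitalized-phase recursion keeping the two death routes separate
    n = len(df)
    surv_hosp = np.ones(n)
    p_disc_by = np.zeros((n, HORIZON + 1))
    p_inpdeath = np.zeros(n)
    disc_alive = np.zeros(n)  # discharged and still alive
    p_pddeath = np.zeros(n)
    for t in range(1, HORIZON + 1):
        ha, hb, hc = h_a[:, t - 1], h_b[:, t - 1], h_c[:, t - 1]
        total = ha + hb
        p_exit = -np.expm1(-total)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.where(total > 0, ha / np.where(total > 0, total, 1.0), 0.0)
        pa = p_exit * fa
        pb = p_exit - pa
        pc = -np.expm1(-hc)
        newly_disc = surv_hosp * pa
        p_inpdeath += surv_hosp * pb
        p_pddeath += disc_alive * pc
        disc_alive = disc_alive * (1 - pc) + newly_disc
        surv_hosp *= 1 - pa - pb
        p_disc_by[:, t] = p_disc_by[:, t - 1] + newly_disc
    p_disc_total = p_disc_by[:, -1].mean()
    los_cdf = p_disc_by.mean(axis=0) / p_disc_by[:, -1].mean()
    return {
        "los_cdf": los_cdf,                      # index = day
        "p_discharged_90": float(p_disc_total),
        "p_inpatient_death_90": float(p_inpdeath.mean()),
        "p_postdischarge_death_90": float(p_pddeath.mean()),
    }


def calibrate_baselines(target_mortality: float = 0.076,
                        inpatient_share: float = 1.0 / 3.0,
                        n_profiles: int = 40000, seed: int = 12345,
                        verbose: bool = False) -> BaselineHazards:
    """Numerically calibrate ``scale_a``, ``b0`` and ``c0`` so the default
    cohort reproduces the marginal anchors (median LOS 8 d, overall 90-day
    mortality ``target_mortality`` split ``inpatient_share`` in hospital).

    Uses the analytic cohort-average recursion (no Monte Carlo noise) and a
    short fixed-point loop over three 1-D root finds.  The shipped defaults
    were produced by this routine; it is exposed so the calibration is
    reproducible.
    """
    base = BaselineHazards()
    target_inp = target_mortality * inpatient_share
    target_pd = target_mortality * (1.0 - inpatient_share)
    for _ in range(3):
        def med_gap(scale):
            b = replace(base, scale_a=float(scale))
            return _population_anchors(b, n_profiles, seed)["los_cdf"][8] - 0.53
        base = replace(base, scale_a=float(optimize.brentq(med_gap, 0.3, 3.0, xtol=1e-4)))

        def inp_gap(log_b0):
            b = replace(base, b0=float(np.exp(log_b0)))
            return _population_anchors(b, n_profiles, seed)["p_inpatient_death_90"] - target_inp
        base = replace(base, b0=float(np.exp(optimize.brentq(inp_gap, np.log(1e-5), np.log(2e-2), xtol=1e-3))))

        def pd_gap(log_c0):
            b = replace(base, c0=float(np.exp(log_c0)))
            return _population_anchors(b, n_profiles, seed)["p_postdischarge_death_90"] - target_pd
        base = replace(base, c0=float(np.exp(optimize.brentq(pd_gap, np.log(1e-5), np.log(2e-2), xtol=1e-3))))
        if verbose:
            print(base, _population_anchors(base, n_profiles, seed))
    return base


#: Calibrated default baselines (output of ``calibrate_baselines()``),
#: frozen so that cohort generation does not depend on re-running the search.
#: The inpatient share of the 7.6% overall mortality is a modelling choice
#: (one third): the registry publication does not report the split.
CALIBRATED_SCALE_A = 0.9332851549067986
CALIBRATED_B0 = 0.002185743626998703
CALIBRATED_C0 = 0.0005925055760849233


def default_baselines() -> BaselineHazards:
    return BaselineHazards(scale_a=CALIBRATED_SCALE_A, b0=CALIBRATED_B0,
                           c0=CALIBRATED_C0)
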