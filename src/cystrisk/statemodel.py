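"""Three-state daily-cycle transition model.

States: hospitalized (everyone starts here), discharged, dead (absorbing).
Each 1-day cycle converts the individualized cause-specific hazards into
transition probabilities and propagates state occupancy deterministically
over 90 cycles.  Within a cycle the two competing exits from the hospitalized
state share the total exit probability proportionally to their hazards
(the exponential joint-survival split), so the daily probabilities can never
leave the simplex.

Time in the living states is accrued with a half-cycle (trapezoidal)
correction — events are treated as occurring mid-cycle — and weighted by
per-day utilities to give 90-day quality-adjusted life days (QALDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOSPITALIZED, DISCHARGED, DEAD = 0, 1, 2


@dataclass
class UtilityWeights:
    """Per-day utility weights of the three health states (dimensionless,
    in [0, 1]; death is anchored at 0)."""
    u_hospitalized: float = 0.67
    u_discharged: float = 0.77
    u_death: float = 0.0

    def __post_init__(self):
        for u in (self.u_hospitalized, self.u_discharged, self.u_death):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {u} outside [0, 1]")
        if self.u_death != 0.0:
            raise ValueError("the death state is anchored at utility 0")


@dataclass
class ModelConfig:
    horizon: int = 90          # cycles of 1 day
    half_cycle: bool = True    # trapezoidal time accrual (mid-cycle events)
    utilities: UtilityWeights = field(default_factory=UtilityWeights)

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class PredictionResult:
    p_death_90: float
    days_hospitalized: float
    days_discharged: float
    qald: float


def daily_transition_probabilities(h_a, h_b, h_c):
    """Convert daily cause-specific hazards into one-cycle probabilities.

    From the hospitalized state the total exit probability is
    ``1 - exp(-(hA + hB))``, split between discharge and inpatient death in
    proportion ``hA : hB``; from the discharged state the death probability
    is ``1 - exp(-hC)``.  Broadcasts over arrays.
    """
    h_a = np.asarray(h_a, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    h_c = np.asarray(h_c, dtype=float)
    if np.any(h_a < 0) or np.any(h_b < 0) or np.any(h_c < 0):
        raise ValueError("hazards must be nonnegative")
    total = h_a + h_b
    p_exit = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(total > 0, h_a / np.where(total > 0, total, 1.0), 0.0)
    p_a = p_exit * frac_a
    p_b = p_exit - p_a
    p_c = -np.expm1(-h_c)
    return p_a, p_b, p_c


def run_trace(h_a, h_b, h_c, horizon: int | None = None) -> np.ndarray:
    """Propagate state occupancy over the daily cycles.

    Parameters
    ----------
    h_a, h_b, h_c : array_like, shape (T,) or (n, T)
        Daily individualized hazards for cycles 1..T (entry ``t-1`` is the
        hazard acting during cycle ``t``).
    horizon : int, optional
        Number of cycles (default: T).

    Returns
    -------
    ndarray, shape (horizon+1, 3) or (n, horizon+1, 3)
        ``occupancy[..., t, s]`` for t = 0..horizon and states
        (hospitalized, discharged, dead); row t sums to 1.
    """
    squeeze = (np.asarray(h_a).ndim == 1 and np.asarray(h_b).ndim == 1
               and np.asarray(h_c).ndim == 1)
    h_a = np.atleast_2d(np.asarray(h_a, dtype=float))
    h_b = np.atleast_2d(np.asarray(h_b, dtype=float))
    h_c = np.atleast_2d(np.asarray(h_c, dtype=float))
    n, T = np.broadcast_shapes(h_a.shape, h_b.shape, h_c.shape)
    horizon = T if horizon is None else horizon
    if horizon > T:
        raise ValueError(f"horizon {horizon} exceeds hazard length {T}")

    p_a, p_b, p_c = daily_transition_probabilities(h_a, h_b, h_c)
    occ = np.zeros((n, horizon + 1, 3))
    occ[:, 0, HOSPITALIZED] = 1.0
    for t in range(1, horizon + 1):
        hosp = occ[:, t - 1, HOSPITALIZED]
        disc = occ[:, t - 1, DISCHARGED]
        dead = occ[:, t - 1, DEAD]
        pa, pb, pc = p_a[:, t - 1], p_b[:, t - 1], p_c[:, t - 1]
        occ[:, t, HOSPITALIZED] = hosp * (1.0 - pa - pb)
        occ[:, t, DISCHARGED] = disc * (1.0 - pc) + hosp * pa
        occ[:, t, DEAD] = dead + hosp * pb + disc * pc
    return occ[0] if squeeze and occ.shape[0] == 1 else occ


def summarize_trace(trace: np.ndarray, config: ModelConfig | None = None):
    """Reduce an occupancy trace to 90-day mortality, expected days per
    living state and QALDs.

    Expected days use trapezoidal (half-cycle) summation when
    ``config.half_cycle`` is set, end-of-cycle occupancy otherwise; the
    mortality probability is always read at the horizon boundary.
    Accepts a single trace ``(T+1, 3)`` or a stack ``(n, T+1, 3)``; returns
    a :class:`PredictionResult` or a DataFrame respectively.
    """
    config = config or ModelConfig()
    single = trace.ndim == 2
    occ = trace[None] if single else trace
    if config.half_cycle:
        days = 0.5 * (occ[:, :-1, :] + occ[:, 1:, :]).sum(axis=1)
    else:
        days = occ[:, 1:, :].sum(axis=1)
    u = config.utilities
    qald = u.u_hospitalized * days[:, HOSPITALIZED] + u.u_discharged * days[:, DISCHARGED]
    p_death = occ[:, -1, DEAD]
    if single:
        return PredictionResult(float(p_death[0]), float(days[0, HOSPITALIZED]),
                                float(days[0, DISCHARGED]), float(qald[0]))
    return pd.DataFrame({
        "p_death_90": p_death,
        "days_hospitalized": days[:, HOSPITALIZED],
        "days_discharged": days[:, DISCHARGED],
        "qald": qald,
    })


def profile_hazards(models, X: pd.DataFrame):
    """Individualized daily hazards for each transition model.

    ``models`` maps ``{"A": HazardModel, "B": ..., "C": ...}``-style keys to
    objects exposing ``daily_h0`` (length-90 array), ``coef`` (dict column ->
    log-HR) and ``age_center``; ``X`` is a cohort-like frame from which the
    needed design columns are built.  Returns three (n, 90) arrays.
    """
    from .cohort import COVARIATE_BLOCKS, design_matrix

    out = []
    for key in ("A", "B", "C"):
        m = models[key]
        blocks = [b for b, cols in COVARIATE_BLOCKS.items()
                  if any(c in m.coef for c in cols)]
        D = design_matrix(X, blocks=blocks, age_center=m.age_center)
        missing = [c for c in m.coef if c not in D.columns]
        if missing:
            raise KeyError(f"profile lacks covariates {missing} for transition {key}")
        lp = sum(m.coef[c] * D[c].to_numpy() for c in m.coef) if m.coef else \
            np.zeros(len(X))
        out.append(np.asarray(m.daily_h0, dtype=float)[None, :] * np.exp(lp)[:, None])
    return tuple(out)


def predict_profiles(models, X: pd.DataFrame,
                     config: ModelConfig | None = None) -> pd.DataFrame:
    """End-to-end individualized prediction for a frame of risk profiles."""
    config = config or ModelConfig()
    h_a, h_b, h_c = profile_hazards(models, X)
    trace = run_trace(h_a, h_b, h_c, horizon=config.horizon)
    if trace.ndim == 2:
        trace = trace[None]
    res = summarize_trace(trace, config)
    res.index = X.index
    return res


def stratify_risk(p_death, thresholds=(0.05, 0.10, 0.15)) -> dict[float, float]:
    """Fraction of profiles with predicted mortality strictly above each
    threshold; nonincreasing in the threshold."""
    p = np.asarray(p_death, dtype=float)
    if p.size == 0:
        raise ValueError("empty predictions")
    return {float(th): float(np.mean(p > th)) for th in thresholds}
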