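import math

import numpy as np
import pandas as pd
import pytest

from cystrisk.cohort import derive_outcomes
from cystrisk.hazards import (HazardModel, aic, backward_select_aic,
                              build_transition_dataset,
                              cox_log_partial_likelihood, fit_cox, pool_models)


class TestTransitionDatasets:
    def test_discharged_then_dead(self, three_row_cohort):
        coded = derive_outcomes(three_row_cohort)
        a = build_transition_dataset(coded, "A")
        b = build_transition_dataset(coded, "B")
        c = build_transition_dataset(coded, "C")
        # subject discharged day 8, dies day 40
        assert (a.loc[2, "time"], a.loc[2, "status"]) == (8, 1)
        assert (b.loc[2, "time"], b.loc[2, "status"]) == (8, 0)
        row = c[c["patient_id"] == "c"].iloc[0]
        assert (row["entry"], row["time"], row["status"]) == (8, 40, 1)

    def test_inpatient_death_has_no_c_row(self, three_row_cohort):
        coded = derive_outcomes(three_row_cohort)
        b = build_transition_dataset(coded, "B")
        c = build_transition_dataset(coded, "C")
        assert (b.loc[1, "time"], b.loc[1, "status"]) == (12, 1)
        assert "b" not in set(c["patient_id"])

    def test_discharged_alive_censored_at_horizon(self, three_row_cohort):
        coded = derive_outcomes(three_row_cohort)
        c = build_transition_dataset(coded, "C")
        row = c[c["patient_id"] == "a"].iloc[0]
        assert (row["entry"], row["time"], row["status"]) == (8, 90, 0)

    def test_no_discharges_rejected(self, three_row_cohort):
        coded = derive_outcomes(three_row_cohort.iloc[[1]])
        with pytest.raises(ValueError, match="discharged"):
            build_transition_dataset(coded, "C")

    def test_ab_events_partition_hospitalized_exits(self, small_coded):
        a = build_transition_dataset(small_coded, "A")
        b = build_transition_dataset(small_coded, "B")
        censored = len(small_coded) - a["status"].sum() - b["status"].sum()
        assert censored >= 0
        assert a["status"].sum() + b["status"].sum() + censored == len(small_coded)


class TestPartialLikelihood:
    def test_null_log_pl_matches_direct_enumeration(self):
        # <=10-row instance with ties and delayed entry
        entry = np.array([0, 0, 0, 2, 2, 0, 3, 0])
        time = np.array([3, 3, 5, 5, 6, 6, 8, 9])
        status = np.array([1, 1, 1, 0, 1, 1, 1, 0])

        def naive_null():
            ll = 0.0
            for t in sorted(set(time[status == 1])):
                d = sum(1 for i in range(len(time)) if time[i] == t and status[i])
                n_risk = sum(1 for i in range(len(time))
                             if entry[i] < t <= time[i])
                for l in range(d):
                    ll -= math.log(n_risk - l)
            return ll

        got = cox_log_partial_likelihood(entry, time, status, np.zeros(8))
        assert got == pytest.approx(naive_null(), abs=1e-12)

    def test_matches_lifelines_at_fitted_coefficients(self, small_coded):
        from cystrisk.cohort import design_matrix

        td = build_transition_dataset(small_coded, "C")
        m = fit_cox(td, ["age", "cci"], age_center=69.0)
        D = design_matrix(td, ["age", "cci"], 69.0)
        lp = sum(m.coef[c] * D[c].to_numpy() for c in m.coef)
        mine = cox_log_partial_likelihood(td["entry"], td["time"], td["status"], lp)
        assert mine == pytest.approx(m.log_likelihood, rel=1e-9)


def _two_group_dataset(n, beta, seed, rate=0.02):
    rng = np.random.default_rng(seed)
    male = rng.random(n) < 0.5
    t = rng.exponential(1.0 / (rate * np.exp(beta * male)))
    status = (t <= 90).astype(int)
    time = np.minimum(t, 90.0)
    df = pd.DataFrame({"sex": np.where(male, "male", "female"),
                       "entry": 0.0, "time": time, "status": status})
    df.attrs["transition"] = "X"
    return df


class TestFitCox:
    def test_two_group_hazard_ratio_recovered(self):
        df = _two_group_dataset(n=4000, beta=math.log(2.0), seed=8)
        m = fit_cox(df, blocks=["sex"], age_center=0.0)
        z = (m.coef["sex_male"] - math.log(2.0)) / m.se["sex_male"]
        assert abs(z) < 2

    def test_constant_covariate_rejected(self):
        df = _two_group_dataset(n=200, beta=0.0, seed=1)
        df["sex"] = "male"
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, blocks=["sex"], age_center=0.0)

    def test_no_events_rejected(self):
        df = _two_group_dataset(n=50, beta=0.0, seed=1)
        df["status"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, blocks=["sex"], age_center=0.0)

    def test_baseline_cumhaz_nondecreasing_and_daily_consistent(self, small_coded):
        td = build_transition_dataset(small_coded, "A")
        m = fit_cox(td, ["age", "sex"], age_center=69.0)
        assert np.all(np.diff(m.baseline_cumhaz) >= 0)
        np.testing.assert_allclose(np.diff(m.baseline_cumhaz), m.daily_h0)
        assert len(m.daily_h0) == 90

    def test_null_model_baseline_is_nelson_aalen_like(self):
        # no covariates: Breslow baseline increments are d_t / n_t
        df = pd.DataFrame({"entry": [0.0] * 4, "time": [2.0, 2.0, 3.0, 5.0],
                           "status": [1, 1, 1, 0]})
        m = fit_cox(df, blocks=[], age_center=0.0)
        assert m.daily_h0[1] == pytest.approx(2 / 4)
        assert m.daily_h0[2] == pytest.approx(1 / 2)


class TestBackwardSelection:
    def test_empty_candidate_set(self, small_coded):
        td = build_transition_dataset(small_coded, "B")
        selected, trace = backward_select_aic(td, blocks=[])
        assert selected == []
        assert len(trace) == 1

    def test_strong_kept_noise_dropped(self):
        """A real effect survives block-wise AIC removal; a null block is
        dropped at roughly the chi-square rate."""
        rng = np.random.default_rng(77)
        kept_strong = dropped_noise = 0
        reps = 100
        for _ in range(reps):
            n = 1200
            male = rng.random(n) < 0.5
            cci = rng.choice(["0", "1", "2plus"], size=n, p=[0.6, 0.3, 0.1])
            t = rng.exponential(1.0 / (0.015 * np.exp(0.7 * male)))
            df = pd.DataFrame({
                "sex": np.where(male, "male", "female"), "cci": cci,
                "entry": 0.0, "time": np.minimum(t, 90.0),
                "status": (t <= 90).astype(int)})
            selected, _ = backward_select_aic(df, blocks=["sex", "cci"],
                                              age_center=0.0)
            kept_strong += "sex" in selected
            dropped_noise += "cci" not in selected
        assert kept_strong / reps >= 0.95
        assert dropped_noise / reps >= 0.70  # expected ~ P(chi2_2 < 4) = 86.5%
        # null-block retention stays below chance
        assert (reps - dropped_noise) / reps < 0.50

    def test_aic_decreases_along_trace(self, small_coded):
        td = build_transition_dataset(small_coded, "B")
        selected, trace = backward_select_aic(td)
        aics = [step["aic"] for step in trace]
        assert all(b < a for a, b in zip(aics, aics[1:]))
        assert set(selected) <= {"age", "sex", "cci", "ct_stage", "volume"}


class TestPooling:
    def _model(self, beta, var, h0=None):
        cumhaz = np.concatenate([[0.0], np.cumsum(h0 if h0 is not None
                                                  else np.full(90, 1e-3))])
        return HazardModel(transition="B", coef={"x": beta},
                           se={"x": math.sqrt(var)}, baseline_cumhaz=cumhaz,
                           daily_h0=np.diff(cumhaz), age_center=69.0)

    def test_identical_models_pool_to_themselves(self):
        models = [self._model(0.5, 0.04) for _ in range(3)]
        p = pool_models(models)
        assert p.coef["x"] == pytest.approx(0.5)
        assert p.se["x"] == pytest.approx(0.2)
        np.testing.assert_allclose(p.baseline_cumhaz, models[0].baseline_cumhaz)

    def test_rubin_arithmetic(self):
        v = 0.04
        models = [self._model(b, v) for b in (0.1, 0.2, 0.3)]
        p = pool_models(models)
        assert p.coef["x"] == pytest.approx(0.2)
        assert p.se["x"] ** 2 == pytest.approx(v + (1 + 1 / 3) * 0.01)

    def test_pooled_baseline_nondecreasing(self):
        rng = np.random.default_rng(3)
        models = [self._model(0.1, 0.01, h0=rng.exponential(1e-3, 90))
                  for _ in range(4)]
        p = pool_models(models)
        assert np.all(np.diff(p.baseline_cumhaz) >= 0)

    def test_mismatched_covariates_rejected(self):
        a = self._model(0.1, 0.01)
        b = self._model(0.1, 0.01)
        b.coef = {"y": 0.1}
        b.se = {"y": 0.1}
        with pytest.raises(ValueError, match="mismatch"):
            pool_models([a, b])
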