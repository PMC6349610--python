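import numpy as np
import pandas as pd
import pytest

from cystrisk.cohort import REGION_LEVELS
from cystrisk.hazards import fit_transition_models
from cystrisk.simulate import GeneratorConfig, generate_cohort, inject_missingness
from cystrisk.statemodel import predict_profiles, stratify_risk
from cystrisk.validate import (c_statistic, calibration_slope,
                               hazard_ratio_table, iecv_split, run_iecv,
                               strata_table)


class TestSplit:
    def test_partition_properties(self, small_cohort):
        splits = iecv_split(small_cohort)
        assert len(splits) == 6
        test_ids = [set(t["patient_id"]) for _, _, t in splits]
        all_test = set().union(*test_ids)
        assert all_test == set(small_cohort["patient_id"])
        for i in range(6):
            for j in range(i + 1, 6):
                assert not (test_ids[i] & test_ids[j])
        for region, train, test in splits:
            assert set(test["region"]) == {region}
            assert region not in set(train["region"])
            assert len(train) + len(test) == len(small_cohort)

    def test_missing_region_rejected(self, small_cohort):
        partial = small_cohort[small_cohort["region"] != "SouthAtlantic"]
        with pytest.raises(ValueError, match="SouthAtlantic"):
            iecv_split(partial)

    def test_unknown_region_rejected(self, small_cohort):
        df = small_cohort.copy()
        df.loc[df.index[0], "region"] = "Atlantis"
        with pytest.raises(ValueError, match="Atlantis"):
            iecv_split(df)


def _oracle_c(lp, entry, time, status):
    """Exhaustive enumeration of usable pairs (independent of the
    vectorized implementation)."""
    num, den = 0.0, 0
    n = len(lp)
    for i in range(n):
        if not status[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            at_risk = entry[j] < time[i] and (
                time[j] > time[i] or (time[j] == time[i] and not status[j]))
            if not at_risk:
                continue
            den += 1
            if lp[i] > lp[j]:
                num += 1
            elif lp[i] == lp[j]:
                num += 0.5
    return num / den if den else None


class TestCStatistic:
    def test_perfect_ranking(self):
        # higher predictor, earlier event, no censoring
        lp = [3.0, 2.0, 1.0, 0.0]
        time = [1, 2, 3, 4]
        assert c_statistic(lp, [0] * 4, time, [1] * 4) == 1.0

    def test_all_ties_give_half(self):
        assert c_statistic([1.0] * 5, [0] * 5, [1, 2, 3, 4, 5], [1] * 5) == 0.5

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            c_statistic([1.0, 2.0], [0, 0], [5, 5], [0, 0])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        time = rng.integers(1, 10, size=n).astype(float)
        entry = np.where(rng.random(n) < 0.4,
                         rng.integers(0, 5, size=n), 0).astype(float)
        keep = entry < time
        entry, time = entry[keep], time[keep]
        n = len(time)
        status = rng.integers(0, 2, size=n)
        lp = rng.integers(-2, 3, size=n).astype(float)
        expected = _oracle_c(lp, entry, time, status)
        if expected is None or not status.any():
            return
        assert c_statistic(lp, entry, time, status) == pytest.approx(expected)

    def test_matches_lifelines_without_truncation(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(3)
        n = 200
        lp = rng.normal(size=n)
        time = np.ceil(rng.exponential(20 * np.exp(-lp)))
        status = (time <= 60).astype(int)
        time = np.minimum(time, 60)
        mine = c_statistic(lp, np.zeros(n), time, status)
        theirs = concordance_index(time, -lp, status)
        assert mine == pytest.approx(theirs)


class TestCalibrationSlope:
    def _dataset(self, seed, beta=1.0, n=2000):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        lp = beta * x
        t = np.ceil(rng.exponential(1.0 / (0.02 * np.exp(lp))))
        status = (t <= 90).astype(int)
        return lp, np.zeros(n), np.minimum(t, 90.0), status

    def test_self_generated_data_gives_unit_slope(self):
        lp, entry, time, status = self._dataset(seed=5)
        slope, se = calibration_slope(lp, entry, time, status, with_se=True)
        assert abs(slope - 1.0) < 2 * se

    def test_halving_by_doubled_predictor(self):
        lp, entry, time, status = self._dataset(seed=6)
        s1, se1 = calibration_slope(lp, entry, time, status, with_se=True)
        s2, se2 = calibration_slope(2 * lp, entry, time, status, with_se=True)
        assert s2 == pytest.approx(s1 / 2, abs=1e-9)

    def test_sign_flip_negates_slope(self):
        lp, entry, time, status = self._dataset(seed=7)
        s = calibration_slope(lp, entry, time, status)
        assert calibration_slope(-lp, entry, time, status) == pytest.approx(-s, abs=1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_slope([1.0, 1.0], [0, 0], [3, 5], [1, 0])


class TestIECV:
    @pytest.fixture(scope="class")
    def iecv_summary(self):
        cohort = generate_cohort(GeneratorConfig(n=12000, seed=13))
        return run_iecv(cohort, seed=13, select=False)

    def test_full_grid_of_results(self, iecv_summary):
        t = iecv_summary.table()
        assert len(t) == 18
        assert set(t["held_out_region"]) == set(REGION_LEVELS)
        assert t["c_statistic"].dropna().between(0, 1).all()

    def test_homogeneous_truth_slopes_center_on_one(self, iecv_summary):
        t = iecv_summary.table()
        mean_slopes = t.groupby("transition")["calibration_slope"].mean()
        assert ((mean_slopes > 0.75) & (mean_slopes < 1.25)).all()

    def test_deterministic_given_seed(self):
        cohort = generate_cohort(GeneratorConfig(n=3000, seed=17))
        a = run_iecv(cohort, seed=3, select=False).table()
        b = run_iecv(cohort, seed=3, select=False).table()
        pd.testing.assert_frame_equal(a, b)

    def test_strict_mode_with_missing_data_runs_leakage_free(self):
        df = generate_cohort(GeneratorConfig(n=6000, seed=19))
        rng = np.random.default_rng(20)
        df = inject_missingness(df, {"volume_cat": {"rate": 0.05}}, rng)
        summary = run_iecv(df, m=2, seed=19, select=False)
        assert len(summary.table()) == 18
        lo, hi = summary.ranges()["calibration_slope"]
        assert np.isfinite(lo) and np.isfinite(hi)


class TestReportTables:
    def test_hr_table_matches_model_coefficients(self, small_coded):
        models = fit_transition_models([small_coded], select=False,
                                       age_center=69.0)
        t = hazard_ratio_table(models)
        for tr in "ABC":
            sub = t[t["transition"] == tr].set_index("covariate")
            for c, b in models[tr].coef.items():
                assert sub.loc[c, "hr"] == pytest.approx(np.exp(b))
                assert sub.loc[c, "ci_low"] < sub.loc[c, "hr"] < sub.loc[c, "ci_high"]

    def test_strata_table_reproduces_stratify_risk(self, small_coded):
        models = fit_transition_models([small_coded], select=False,
                                       age_center=69.0)
        preds = predict_profiles(models, small_coded)
        table = strata_table(preds)
        frac = stratify_risk(preds["p_death_90"])
        for _, row in table.iterrows():
            assert row["proportion"] == frac[row["threshold"]]

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            strata_table(pd.DataFrame({"p_death_90": []}))
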