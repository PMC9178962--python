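"""Deviation computation, age categories, accelerated-ageing direction."""
import numpy as np
import pandas as pd
import pytest

import msageing as msa
from msageing.deviations import AgeCategory
from conftest import bh_qvalues


def enumerated_direction(a1, a2, cat):
    """Independent oracle: the four enumerated direction rules, written out
    case by case from the trajectory class and turning-point position."""
    cls = msa.classify_trajectory(a1, a2)
    if cls == "increasing":
        return 1
    if cls == "decreasing":
        return -1
    tp = msa.turning_point(a1, a2)
    if cls == "convex":        # rises early, falls late (single peak)
        if tp >= cat.hi:
            return 1           # category sits on the rising limb
        if tp <= cat.lo:
            return -1          # category sits on the falling limb
        return 0
    # concave: falls early, rises late (single trough)
    if tp >= cat.hi:
        return -1
    if tp <= cat.lo:
        return 1
    return 0


@pytest.fixture(scope="module")
def fitted_model(small_cohort):
    demo, ms = small_cohort
    return msa.NormativeTrajectoryModel().fit(demo["age"], ms)


class TestAgeCategories:
    @pytest.mark.parametrize("age,label", [
        (25, "20-30"), (30, "30-35"), (35, "35-40"), (44.9, "40-45"),
        (45, "45-60"), (60, "45-60")])
    def test_half_open_partition(self, age, label):
        assert msa.assign_age_category(age).label == label

    def test_uncovered_age_errors_by_default(self):
        with pytest.raises(ValueError, match="not covered"):
            msa.assign_age_category(18.0)

    def test_drop_policy_returns_none(self):
        assert msa.assign_age_category(18.0, policy="drop") is None

    def test_invalid_category(self):
        with pytest.raises(ValueError):
            AgeCategory(30, 30)


class TestComputeDeviations:
    def test_zero_when_observed_equals_predicted(self, small_cohort,
                                                 fitted_model):
        demo, ms = small_cohort
        covered = demo[demo["age"].between(20, 60)]
        predicted = pd.DataFrame(
            fitted_model.predict(covered["age"]),
            index=pd.Index(covered["subject_id"], name="subject_id"),
            columns=fitted_model.regions_)
        records = msa.compute_deviations(predicted, covered, fitted_model)
        np.testing.assert_allclose(records["deviation"], 0, atol=1e-12)

    def test_sign_convention_observed_minus_predicted(self):
        """Trajectory predicts 0.30 at age 40; observed 0.25 -> -0.05."""
        trajs = [msa.TrajectorySpec("A", 0.46, -0.004, 0.0, noise_sd=0.0),
                 msa.TrajectorySpec("B", -0.08, 0.002, 0.0, noise_sd=0.0)]
        demo = pd.DataFrame({"subject_id": ["s"] * 1, "age": [40.0],
                             "sex": ["F"], "group": ["patient"]})
        norm = msa.sample_cohort(msa.CohortSpec(30, (20, 60), seed=1))
        ms_norm = msa.generate_regional_ms(norm, trajs, seed=2)
        model = msa.NormativeTrajectoryModel().fit(norm["age"], ms_norm)
        obs = pd.DataFrame([[0.25, 0.0]],
                           index=pd.Index(["s"], name="subject_id"),
                           columns=["A", "B"])
        records = msa.compute_deviations(obs, demo, model)
        dev = records.set_index("region")["deviation"]
        assert dev["A"] == pytest.approx(-0.05, abs=1e-9)
        assert records.attrs["sign_convention"] == "observed_minus_predicted"

    def test_normative_null_mean_deviation_near_zero(self, small_truth):
        """Cohort drawn from the normative process deviates from the refit
        model by ~0 per region (within 3 SE)."""
        demo = msa.sample_cohort(msa.CohortSpec(300, (20, 80), seed=3))
        ms = msa.generate_regional_ms(demo, small_truth, seed=4)
        model = msa.NormativeTrajectoryModel().fit(demo["age"], ms)
        fresh = msa.sample_cohort(msa.CohortSpec(300, (20, 60), seed=5))
        ms_fresh = msa.generate_regional_ms(fresh, small_truth, seed=6)
        records = msa.compute_deviations(ms_fresh, fresh, model)
        stats = records.groupby("region")["deviation"].agg(["mean", "std",
                                                            "count"])
        z = stats["mean"] / (stats["std"] / np.sqrt(stats["count"]))
        assert (np.abs(z) <= 3).mean() >= 0.9

    def test_extrapolation_flagged(self, small_cohort, fitted_model):
        demo, ms = small_cohort
        young = demo.copy()
        young.loc[young.index[0], "age"] = 25.0
        # force ages beyond the fitted range for one subject
        fitted_model.age_range_ = (30.0, 80.0)
        try:
            records = msa.compute_deviations(ms, young, fitted_model)
            flagged = records.loc[records["subject_id"]
                                  == young["subject_id"].iloc[0]]
            assert flagged["extrapolated"].all()
        finally:
            fitted_model.age_range_ = (
                float(demo["age"].min()), float(demo["age"].max()))


class TestTestDeviations:
    def _records(self, deviations, ages=None):
        n, r = deviations.shape
        ages = np.full(n, 25.0) if ages is None else ages
        rows = []
        for i in range(n):
            for j in range(r):
                rows.append({"subject_id": f"s{i}", "region": f"r{j}",
                             "deviation": deviations[i, j],
                             "age": ages[i],
                             "age_category":
                                 msa.assign_age_category(ages[i]).label,
                             "extrapolated": False})
        return pd.DataFrame(rows)

    def _flat_model(self, n_regions, a1=-0.002):
        trajs = [msa.TrajectorySpec(f"r{j}", 0.2, a1, 0.0, noise_sd=0.0)
                 for j in range(n_regions)]
        demo = msa.sample_cohort(msa.CohortSpec(30, (20, 60), seed=7))
        ms = msa.generate_regional_ms(demo, trajs, seed=8)
        return msa.NormativeTrajectoryModel().fit(demo["age"], ms)

    def test_all_zero_deviations_nothing_significant(self):
        model = self._flat_model(5)
        res = msa.test_deviations(self._records(np.zeros((10, 5))), model)
        assert not res["significant"].any()
        assert res["degenerate"].all()

    def test_t_statistic_matches_hand_formula_and_bh(self):
        """Mean -0.05, SD 0.05, n = 40 -> t = -0.05/(0.05/sqrt(40)) ~ -6.3,
        q < 0.01 under the hand-rolled BH oracle."""
        rng = np.random.default_rng(9)
        d = rng.normal(size=(40, 6))
        d = (d - d.mean(axis=0)) / d.std(axis=0, ddof=1)
        d = d * 0.05
        d[:, 0] += -0.05              # exact sample mean/SD in region 0
        model = self._flat_model(6)
        res = msa.test_deviations(self._records(d), model)
        r0 = res.set_index("region").loc["r0"]
        assert r0["t"] == pytest.approx(-0.05 / (0.05 / np.sqrt(40)),
                                        abs=1e-9)
        np.testing.assert_allclose(
            res["q"], bh_qvalues(res["p"].to_numpy()), atol=1e-12)
        assert r0["q"] < 0.01
        assert r0["significant"] and r0["accelerated_consistent"] is True

    def test_global_null_rarely_flags(self):
        rng = np.random.default_rng(10)
        model = self._flat_model(40)
        rates = []
        for _ in range(20):
            d = rng.normal(0, 0.05, size=(30, 40))
            res = msa.test_deviations(self._records(d), model)
            rates.append(res["significant"].mean())
        assert np.mean(rates) <= 0.01

    def test_sign_flip_permutation_agrees_with_t(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.03, 0.05, size=(35, 4))
        model = self._flat_model(4)
        res = msa.test_deviations(self._records(d), model, n_perm=999,
                                  seed=1)
        # strong shifts: parametric and permutation p agree on significance
        strong = res[np.abs(res["t"]) > 4]
        assert (strong["perm_p"] < 0.01).all()

    def test_q_at_least_p(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0, 0.05, size=(20, 15))
        model = self._flat_model(15)
        res = msa.test_deviations(self._records(d), model)
        assert (res["q"] >= res["p"] - 1e-12).all()


class TestAcceleratedDirection:
    cat_20_30 = AgeCategory(20, 30)
    cat_35_40 = AgeCategory(35, 40)

    def test_decreasing_negative_deviations_accelerated(self):
        # decreasing trajectory: deviations below the curve look "older"
        assert msa.accelerated_direction(-0.002, 0.0,
                                         AgeCategory(27, 60)) == -1

    def test_increasing_positive_deviations_accelerated(self):
        assert msa.accelerated_direction(0.002, 0.0,
                                         AgeCategory(27, 60)) == 1

    def test_convex_turning_point_above_category(self):
        # turning point 43.5 years; young category entirely on rising limb
        a1, a2 = 0.0087, -0.0001
        assert msa.turning_point(a1, a2) == pytest.approx(43.5)
        assert msa.accelerated_direction(a1, a2, self.cat_20_30) == 1

    def test_convex_turning_point_below_category(self):
        a1, a2 = 0.006, -0.0001   # turning point at 30
        assert msa.accelerated_direction(a1, a2, AgeCategory(35, 45)) == -1

    def test_concave_mirrors_convex(self):
        a1, a2 = -0.0087, 0.0001
        assert msa.accelerated_direction(a1, a2, self.cat_20_30) == -1
        assert msa.accelerated_direction(a1, a2, AgeCategory(45, 60)) == 1

    def test_turning_point_inside_category_indeterminate(self):
        a1, a2 = 0.0074, -0.0001  # turning point at 37
        assert msa.accelerated_direction(a1, a2, self.cat_35_40) == 0

    def test_uniform_rule_matches_enumerated_rules(self):
        """The slope-sign rule and the four enumerated case rules agree on
        1000 random trajectory × category pairs.

        Categories are drawn within the reference span [27, 60], where the
        equivalence is provable; outside it (a turning point in [20, 27))
        the class labels no longer describe the curve inside the category
        and the slope-sign rule is strictly more faithful.
        """
        rng = np.random.default_rng(13)
        for _ in range(1000):
            a1 = rng.normal(0, 0.006)
            a2 = rng.choice([-1, 1]) * rng.uniform(1e-6, 2e-4)
            lo = rng.uniform(27, 55)
            cat = AgeCategory(lo, rng.uniform(lo + 1, 60))
            assert (msa.accelerated_direction(a1, a2, cat)
                    == enumerated_direction(a1, a2, cat)), (a1, a2, cat)


class TestSummaries:
    def _results(self, rows):
        return pd.DataFrame(rows)

    def test_no_significant_regions_reports_na(self):
        res = self._results([
            {"region": "a", "age_category": "20-30", "significant": False,
             "accelerated_consistent": None, "accelerated_direction": 1}])
        summary = msa.summarize_deviations(res)
        assert summary["overall"]["pct_consistent"] is None

    def test_all_consistent_is_hundred_percent(self):
        res = self._results([
            {"region": r, "age_category": "20-30", "significant": True,
             "accelerated_consistent": True, "accelerated_direction": -1}
            for r in "abc"])
        summary = msa.summarize_deviations(res)
        assert summary["overall"]["pct_consistent"] == 100.0
        assert summary["overall"]["n_significant_regions"] == 3

    def test_injection_detected_as_consistent(self, small_truth):
        """+10-year injection into decreasing regions yields negative mean
        deviations flagged accelerated-consistent."""
        norm = msa.sample_cohort(msa.CohortSpec(400, (20, 80), seed=14))
        ms_norm = msa.generate_regional_ms(norm, small_truth, seed=15)
        model = msa.NormativeTrajectoryModel().fit(norm["age"], ms_norm)
        patients = msa.sample_cohort(msa.CohortSpec(
            183, (20, 59), group="patient", seed=16))
        affected = msa.simulate.decreasing_regions(small_truth)
        ms_pat = msa.generate_regional_ms(
            patients, small_truth, msa.AgedInjectionSpec(10.0, affected),
            seed=17)
        records = msa.compute_deviations(ms_pat, patients, model)
        res = msa.test_deviations(records, model)
        hit = res[res["region"].isin(affected) & res["significant"]]
        assert len(hit) > 0
        assert (hit["mean_deviation"] < 0).all()
        assert hit["accelerated_consistent"].astype(bool).mean() >= 0.95
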