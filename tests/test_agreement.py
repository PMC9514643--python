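"""Observer agreement: ICC(2,1), bands, descriptives, outcome groups."""

import numpy as np
import pandas as pd
import pytest

import gaparea3d as g3
from gaparea3d.agreement import (ObserverTable, OutcomeRecord,
                                 band, icc_single_rater, median_iqr,
                                 observer_median_difference,
                                 outcome_group_summary)


def _table(rows, kind="gap_area_mm2"):
    arr = np.asarray(rows, dtype=float)
    cols = [f"observer_{j + 1}" for j in range(arr.shape[1])]
    return ObserverTable(data=pd.DataFrame(arr, columns=cols), kind=kind)


def anova_icc_oracle(x):
    """ICC(2,1) from explicitly summed ANOVA squares (independent route)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement_is_one(self):
        r = icc_single_rater(_table([[1, 1], [2, 2], [3, 3]]))
        assert r.estimate == pytest.approx(1.0)
        assert r.band == "excellent"

    def test_constant_observer_shift_lowers_absolute_agreement(self):
        base = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        shifted = base.copy()
        shifted[:, 1] += 2.0  # one rater biased by +2, zero residual noise
        r = icc_single_rater(_table(shifted))
        assert r.estimate < 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_summed_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(30, 8, size=(6, 3)) + rng.normal(0, 4, size=(6, 1))
        r = icc_single_rater(_table(x))
        assert r.estimate == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(123)
        x = rng.normal(50, 10, size=(12, 3)) + rng.normal(0, 5, size=(12, 1))
        r = icc_single_rater(_table(x))
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 3),
            "raters": np.tile(np.arange(3), 12),
            "score": x.ravel()})
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="score")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert r.estimate == pytest.approx(row.ICC, abs=1e-10)
        assert r.ci_low == pytest.approx(row.CI95[0], abs=0.01)
        assert r.ci_high == pytest.approx(row.CI95[1], abs=0.01)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_single_rater(_table([[5, 5], [5, 5], [5, 5]]))

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(9)
        x = rng.normal(40, 6, size=(8, 3)) + rng.normal(0, 3, size=(8, 1))
        r0 = icc_single_rater(_table(x))
        r1 = icc_single_rater(_table(x * 3.7 + 11.0))
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-12)

    def test_confidence_interval_brackets_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(40, 6, size=(10, 3)) + rng.normal(0, 3, size=(10, 1))
        r = icc_single_rater(_table(x))
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_simulation_limits(self):
        near_perfect = g3.simulate_observer_table(
            20, 3, subject_sd=5.0, observer_bias_sd=0.0, error_sd=1e-6, seed=0)
        assert icc_single_rater(near_perfect).estimate > 0.999
        no_signal = g3.simulate_observer_table(
            20, 3, subject_sd=0.0, observer_bias_sd=0.0, error_sd=3.0, seed=0)
        assert icc_single_rater(no_signal).estimate < 0.3


class TestBands:
    @pytest.mark.parametrize("value,expected", [
        (0.21, "poor"),
        (0.399999, "poor"),
        (0.40, "fair"),
        (0.54, "fair"),
        (0.59, "fair"),
        (0.60, "good"),
        (0.74, "good"),
        (0.75, "excellent"),
        (0.81, "excellent"),
        (0.98, "excellent"),
    ])
    def test_boundaries_exact(self, value, expected):
        assert band(value) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            band(float("nan"))


class TestDescriptives:
    def test_median_iqr_small_sample(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5])
        assert (med, q1, q3) == (3.0, 2.0, 4.0)

    def test_single_value_collapses(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2.0, 20.0, size=40)
        med, q1, q3 = median_iqr(v)
        s = np.sort(v)

        def interp_quantile(p):
            h = (len(s) - 1) * p
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert med == pytest.approx(interp_quantile(0.5), abs=1e-12)
        assert q1 == pytest.approx(interp_quantile(0.25), abs=1e-12)
        assert q3 == pytest.approx(interp_quantile(0.75), abs=1e-12)


class TestObserverDifferences:
    def test_identical_observers_zero_difference(self):
        med, _, _ = observer_median_difference(_table([[10, 10, 10],
                                                       [4, 4, 4]]))
        assert med == 0.0

    def test_pooled_pairwise_differences(self):
        med, _, _ = observer_median_difference(_table([[10, 12, 14],
                                                       [10, 12, 14]]))
        # per case pairwise diffs {2, 2, 4}: pooled median 2
        assert med == 2.0

    def test_two_column_table_equals_repeat_differences(self):
        x = [[10.0, 13.0], [20.0, 21.0], [5.0, 9.0]]
        pooled = observer_median_difference(_table(x), mode="pooled")
        per_case = observer_median_difference(_table(x), mode="per_case")
        expected = median_iqr([3.0, 1.0, 4.0])
        assert pooled == pytest.approx(expected)
        assert per_case == pytest.approx(expected)


class TestOutcomeGroups:
    def _records(self, groups):
        return [OutcomeRecord(str(i), dash=float(d), prwe=float(p),
                              displacement_group=grp)
                for i, (d, p, grp) in enumerate(groups)]

    def test_all_in_one_group_reports_empty_other(self):
        recs = self._records([(5, 10, "above"), (7, 12, "above")])
        out = outcome_group_summary(recs)
        assert out["below"]["count"] == 0 and "dash" not in out["below"]
        assert out["above"]["count"] == 2

    def test_singleton_groups_report_their_records(self):
        recs = self._records([(5, 10, "below"), (7, 12, "above")])
        out = outcome_group_summary(recs)
        assert out["below"]["dash"]["median"] == 5.0
        assert out["above"]["prwe"]["median"] == 12.0

    def test_split_cohort_counts_and_medians(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0, 80, size=(40, 2))
        groups = ["below"] * 6 + ["above"] * 34
        recs = self._records([(d, p, g) for (d, p), g in zip(scores, groups)])
        out = outcome_group_summary(recs)
        assert out["below"]["count"] == 6
        assert out["above"]["count"] == 34
        assert out["above"]["dash"]["median"] == pytest.approx(
            float(np.median(scores[6:, 0])))

    def test_score_range_validated(self):
        with pytest.raises(ValueError):
            OutcomeRecord("x", dash=120.0, prwe=0.0,
                          displacement_group="below")


class TestTableValidation:
    def test_incomplete_cases_dropped(self):
        df = pd.DataFrame({"observer_1": [1.0, 2.0, np.nan, 4.0],
                           "observer_2": [1.5, 2.5, 3.0, 4.5]})
        t = ObserverTable(data=df)
        assert t.n_cases == 3

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            ObserverTable(data=pd.DataFrame({"observer_1": [1.0, 2.0]}))

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("case_id,observer_1,observer_2,observer_3\n"
                        "1,30,32,35\n2,60,58,61\n3,12,15,13\n")
        t = ObserverTable.from_csv(path, kind="gap_area_mm2")
        assert t.n_cases == 3 and t.n_observers == 3
        assert icc_single_rater(t).estimate > 0.9
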