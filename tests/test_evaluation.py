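"""Metrics vs independent oracles, bootstrap behaviour, delta labelling,
subgroup splits, Bland-Altman and task orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn import metrics as skm

from helpers import brute_auroc
from wearfit import evaluation as ev
from wearfit.evaluation import (
    EvaluationReport,
    SplitPlan,
    auroc,
    bland_altman,
    bootstrap_ci,
    build_split_plan,
    make_delta_labels,
    metric_suite,
    subgroup_sensitivity,
)


class TestMetricSuite:
    def test_perfect_predictions(self):
        y = np.array([30.0, 35.0, 40.0, 45.0])
        m = metric_suite(y, y)
        assert m["rmse"] == 0 and m["mae"] == 0 and m["mape"] == 0
        assert m["r2"] == 1.0 and m["pearson_r"] == 1.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metric_suite(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metric_suite(np.ones(5), np.arange(5.0))

    def test_matches_reference_library_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(5, 300))
            y = rng.normal(40, 5, n)
            p = y + rng.normal(0, 3, n)
            m = metric_suite(y, p)
            assert m["r2"] == pytest.approx(skm.r2_score(y, p), abs=1e-10)
            assert m["mse"] == pytest.approx(skm.mean_squared_error(y, p), abs=1e-10)
            assert m["rmse"] == pytest.approx(np.sqrt(skm.mean_squared_error(y, p)),
                                             abs=1e-10)
            assert m["mae"] == pytest.approx(skm.mean_absolute_error(y, p), abs=1e-10)
            assert m["mape"] == pytest.approx(
                skm.mean_absolute_percentage_error(y, p), abs=1e-10)
            assert m["pearson_r"] == pytest.approx(sps.pearsonr(y, p)[0], abs=1e-10)
            assert m["std_mae"] == pytest.approx(np.std(np.abs(p - y)), abs=1e-10)


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_chance_level_under_permutation(self):
        rng = np.random.default_rng(1)
        y = rng.permutation(np.repeat([0, 1], 1000))
        s = rng.normal(size=2000)
        assert 0.47 <= auroc(y, s) <= 0.53

    def test_matches_pairwise_oracle_and_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(8, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.normal(size=n), 1)  # coarse scores force ties
            got = auroc(y, s)
            assert got == pytest.approx(brute_auroc(y, s), abs=1e-12)
            assert got == pytest.approx(skm.roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.5, 0.9])


class TestBootstrap:
    def test_zero_variance_statistic_gives_degenerate_interval(self):
        y = np.arange(10.0)
        point, lo, hi = bootstrap_ci(y, y, "rmse", n_boot=100, seed=0)
        assert (point, lo, hi) == (0.0, 0.0, 0.0)

    def test_same_seed_identical_intervals(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        p = y + rng.normal(size=200)
        assert bootstrap_ci(y, p, "r2", seed=9) == bootstrap_ci(y, p, "r2", seed=9)

    def test_interval_brackets_point_for_regression_metrics(self):
        rng = np.random.default_rng(4)
        y = rng.normal(40, 5, 300)
        p = y + rng.normal(0, 2, 300)
        for metric in ("rmse", "r2", "pearson_r", "mae"):
            point, lo, hi = bootstrap_ci(y, p, metric, n_boot=200, seed=1)
            assert lo <= point <= hi


class TestDeltaLabels:
    def test_median_split_keeps_everyone(self):
        deltas = pd.Series(np.arange(1.0, 11.0),
                           index=[f"P{i}" for i in range(10)])
        labels = make_delta_labels(deltas, 0.5, 0.5)
        assert len(labels.labels) == 10
        assert (labels.labels == 0).sum() == 5 and (labels.labels == 1).sum() == 5

    def test_decile_tails_drop_the_middle(self):
        deltas = pd.Series(np.arange(1.0, 101.0),
                           index=[f"P{i:03d}" for i in range(100)])
        labels = make_delta_labels(deltas, 0.1, 0.9)
        assert (labels.labels == 0).sum() == 10
        assert (labels.labels == 1).sum() == 10
        assert set(deltas[labels.labels[labels.labels == 0].index]) == set(range(1, 11))
        assert set(deltas[labels.labels[labels.labels == 1].index]) == set(range(91, 101))

    def test_thresholds_come_from_training_portion_only(self):
        deltas = pd.Series(np.arange(1.0, 101.0),
                           index=[f"P{i:03d}" for i in range(100)])
        train = [f"P{i:03d}" for i in range(50)]  # values 1..50
        labels = make_delta_labels(deltas, 0.2, 0.8, train_ids=train)
        assert labels.lower_threshold == pytest.approx(
            np.quantile(np.arange(1.0, 51.0), 0.2))
        # perturbing test-portion deltas must not move the thresholds
        perturbed = deltas.copy()
        perturbed.iloc[50:] += 1000.0
        again = make_delta_labels(perturbed, 0.2, 0.8, train_ids=train)
        assert again.lower_threshold == labels.lower_threshold
        assert again.upper_threshold == labels.upper_threshold

    def test_ties_leave_classes_balanced_within_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            vals = rng.integers(-3, 4, n).astype(float)  # heavy ties
            deltas = pd.Series(vals, index=[f"P{i:03d}" for i in range(n)])
            try:
                labels = make_delta_labels(deltas, 0.2, 0.8)
            except ValueError:
                continue  # degenerate draw cannot form both tails
            n0 = int((labels.labels == 0).sum())
            n1 = int((labels.labels == 1).sum())
            assert abs(n0 - n1) <= 1
            # brute check: kept ids are the most extreme admissible ones
            kept0 = set(labels.labels[labels.labels == 0].index)
            admissible0 = deltas[deltas <= labels.lower_threshold]
            worst_kept = max((deltas[i], i) for i in kept0)
            dropped = [(v, i) for i, v in admissible0.items() if i not in kept0]
            assert all(d >= worst_kept for d in dropped)

    def test_invalid_quantiles_rejected(self):
        deltas = pd.Series(np.arange(10.0), index=[f"P{i}" for i in range(10)])
        with pytest.raises(ValueError):
            make_delta_labels(deltas, 0.6, 0.9)
        with pytest.raises(ValueError):
            make_delta_labels(deltas, 0.0, 0.9)


class TestSubgroups:
    def _data(self, n=200, seed=7):
        rng = np.random.default_rng(seed)
        ids = [f"P{i:03d}" for i in range(n)]
        truth = pd.Series(rng.normal(40, 5, n), index=ids)
        pred = truth + rng.normal(0, 2, n)
        cov = pd.DataFrame({
            "sex": rng.choice(["female", "male"], n),
            "age": rng.normal(48, 10, n),
            "weight": rng.normal(75, 12, n),
            "bmi": rng.normal(26, 4, n),
            "height": rng.normal(1.7, 0.08, n),
        }, index=ids)
        return truth, pred, cov

    def test_median_goes_to_first_group(self):
        truth, pred, cov = self._data()
        cov["age"] = 48.0
        with pytest.warns(UserWarning):
            rows = subgroup_sensitivity(truth, pred, cov, "age", n_boot=20)
        assert len(rows) == 1
        assert rows[0].n == len(truth)
        assert rows[0].subgroup.startswith("age<=")

    def test_distinct_values_split_evenly(self):
        truth, pred, cov = self._data()
        rows = subgroup_sensitivity(truth, pred, cov, "age", n_boot=20)
        assert abs(rows[0].n - rows[1].n) <= 1
        assert rows[0].n + rows[1].n == len(truth)

    def test_sex_grouping_partitions_ids(self):
        truth, pred, cov = self._data()
        rows = subgroup_sensitivity(truth, pred, cov, "sex", n_boot=20)
        assert len(rows) == 2
        assert rows[0].n + rows[1].n == len(truth)
        for row in rows:
            assert set(row.metrics) == {"rmse", "mse", "r2", "pearson_r",
                                        "mae", "std_mae", "mape"}


class TestBlandAltman:
    def test_identity(self):
        y = np.arange(10.0)
        ba = bland_altman(y, y)
        assert (ba["mean_difference"], ba["lower_limit"], ba["upper_limit"]) \
            == (0.0, 0.0, 0.0)

    def test_constant_bias(self):
        y = np.arange(10.0)
        ba = bland_altman(y, y + 2.0)
        assert ba["mean_difference"] == pytest.approx(2.0)
        assert ba["lower_limit"] == pytest.approx(2.0)
        assert ba["upper_limit"] == pytest.approx(2.0)

    def test_gaussian_limits_near_1_96_sd(self):
        rng = np.random.default_rng(8)
        y = rng.normal(40, 5, 10_000)
        p = y + rng.normal(0, 1, 10_000)
        ba = bland_altman(y, p)
        assert ba["upper_limit"] == pytest.approx(ba["mean_difference"] + 1.96,
                                                  abs=0.05)
        assert ba["lower_limit"] == pytest.approx(ba["mean_difference"] - 1.96,
                                                  abs=0.05)
        assert len(ba["coordinates"]) == 10_000


class TestReportsAndPlans:
    def test_report_roundtrip(self):
        report = EvaluationReport(task="task1_current", model="dense", subgroup="all",
                                  n=100, metrics={"r2": (0.8, 0.75, 0.84)})
        assert EvaluationReport.from_json_obj(report.to_json_obj()) == report

    def test_report_rejects_nonbracketing_interval(self):
        with pytest.raises(ValueError):
            EvaluationReport(task="t", model="m", subgroup="all", n=1,
                             metrics={"r2": (0.9, 0.1, 0.5)})

    def test_split_plan_partitions(self):
        baseline = [f"P{i}" for i in range(100)]
        longitudinal = baseline[60:]
        plan = build_split_plan(baseline, longitudinal, seed=0)
        assert set(plan.task1_train) == set(baseline[:60])
        assert set(plan.task2_train) | set(plan.task2_test) == set(longitudinal)
        assert not set(plan.task2_train) & set(plan.task2_test)
        assert len(plan.task2_test) == 8
        assert SplitPlan.from_json(plan.to_json()) == plan

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(task1_train=["A"], task1_test=["A"],
                      task2_train=["A"], task2_test=[])


class TestRunTask:
    def test_unknown_task_rejected(self, small_bundle):
        _, bundle = small_bundle
        with pytest.raises(ValueError, match="unknown task"):
            ev.run_task("task9", bundle)

    def test_task1_reports_one_row_per_configuration(self, task1_result):
        labels = [r.model for r in task1_result.reports]
        assert labels == [
            "linear:anthro", "linear:rhr", "linear:anthro+rhr",
            "linear:anthro+rhr+sensors", "dense:anthro+rhr+sensors",
            "equation:age+rhr",
        ]

    def test_task3_requires_artifacts(self, small_bundle):
        _, bundle = small_bundle
        with pytest.raises(ValueError, match="task3"):
            ev.run_task("task3_reuse", bundle)

    def test_task3_no_change_limit(self, small_bundle):
        """Identical sensor weeks at both phases -> predicted deltas
        concentrate at exactly zero."""
        _, bundle = small_bundle
        import dataclasses as dc
        frozen = dc.replace(bundle, features_followup=bundle.features_baseline)
        r1 = ev.run_task("task1_current", frozen, seed=0, n_boot=10)
        r3 = ev.run_task("task3_reuse", frozen, plan=r1.artifacts["plan"],
                         artifacts=r1.artifacts, seed=0, n_boot=10)
        preds = r3.artifacts["task3_predictions"]
        delta = preds["pred_current"] - preds["pred_future"]
        assert np.abs(delta.mean()) < 0.5
        assert np.allclose(delta, 0.0)

    def test_task2_regression_rows(self, study_bundle, task1_result):
        _, bundle = study_bundle
        res = ev.run_task("task2_future", bundle,
                          plan=task1_result.artifacts["plan"],
                          artifacts=task1_result.artifacts, seed=0, n_boot=20)
        assert [r.model for r in res.reports] == ["dense:current", "dense:future"]
        for r in res.reports:
            assert np.isfinite(r.metrics["r2"][0])
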