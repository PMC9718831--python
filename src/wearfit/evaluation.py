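"""Task designs, metrics, bootstrap intervals and agreement analyses.

Three evaluation designs mirror the study protocol:

* **Task 1** — train on baseline-only participants, externally validate
  on the longitudinal participants (current VO2max), across the model
  ladder: anthropometrics, RHR, anthropometrics+RHR, the comprehensive
  sensor set, plus the equation baseline and the dense network.
* **Task 2** — retrain on the longitudinal set (80/20) to predict
  current VO2max, future VO2max and their delta (current - future);
  the delta is additionally binarized at the 50/50, 80/20 and 90/10
  quantile designs and attacked with the small sigmoid classifier.
* **Task 3** — reuse the frozen Task-1 model and transforms on the
  follow-up sensor weeks: no retraining, only new data.

All headline statistics come with 95% percentile-bootstrap confidence
intervals (500 resamples by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wearfit._dense import DenseNetConfig
from wearfit import models as wm
from wearfit import transforms as wt
from wearfit.features import default_registry, select_inputs

logger = logging.getLogger(__name__)

SUBGROUP_VARIABLES = ("sex", "age", "weight", "bmi", "height")

#: The model-input ladder evaluated in Task 1, by feature tags.
TASK1_CONFIGURATIONS = (
    ("linear", frozenset({"anthro"})),
    ("linear", frozenset({"rhr"})),
    ("linear", frozenset({"anthro", "rhr"})),
    ("linear", frozenset({"anthro", "rhr", "sensors"})),
    ("dense_regressor", frozenset({"anthro", "rhr", "sensors"})),
)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metric_suite(truth, predictions) -> dict[str, float]:
    """RMSE, MSE, R^2, Pearson r, MAE, SD of absolute error, MAPE."""
    y = np.asarray(truth, float)
    p = np.asarray(predictions, float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("truth and predictions must be equal-length vectors")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("truth is constant; R^2 and Pearson r are undefined")
    err = p - y
    abs_err = np.abs(err)
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r = float(np.corrcoef(y, p)[0, 1]) if np.ptp(p) > 0 else 0.0
    nz = y != 0  # MAPE is undefined at zero truth; restrict to nonzero entries
    mape = float(np.mean(abs_err[nz] / np.abs(y[nz]))) if nz.any() else float("nan")
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mse": float(np.mean(err**2)),
        "r2": 1.0 - ss_res / ss_tot,
        "pearson_r": r,
        "mae": float(abs_err.mean()),
        "std_mae": float(abs_err.std()),
        "mape": mape,
    }


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random
    negative, with 0.5 credit for ties.
    """
    y = np.asarray(labels, float)
    s = np.asarray(scores, float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


_NAMED_METRICS: dict[str, Callable] = {
    "auroc": auroc,
    **{name: (lambda t, p, _n=name: metric_suite(t, p)[_n])
       for name in ("rmse", "mse", "r2", "pearson_r", "mae", "std_mae", "mape")},
}


def bootstrap_ci(truth, predictions, metric, n_boot: int = 500,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float, float]:
    """Point estimate and percentile bootstrap interval of a paired metric.

    ``metric`` is a name from the metric suite (or ``"auroc"``) or any
    callable ``metric(truth, predictions)``.  Resamples on which the
    metric is undefined (e.g. a single-class bootstrap draw) are
    redrawn; the redraw count is logged.
    """
    fn = _NAMED_METRICS[metric] if isinstance(metric, str) else metric
    y = np.asarray(truth, float)
    p = np.asarray(predictions, float)
    point = float(fn(y, p))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = []
    redraws = 0
    while len(values) < n_boot:
        idx = rng.integers(0, y.size, y.size)
        try:
            values.append(float(fn(y[idx], p[idx])))
        except ValueError:
            redraws += 1
            if redraws > 100 * n_boot:
                raise ValueError("metric undefined on virtually every resample")
    if redraws:
        logger.info("bootstrap_ci redrew %d invalid resamples", redraws)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    return point, float(low), float(high)


def bland_altman(truth, predictions) -> dict:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD).

    Differences are prediction minus truth; per-pair (mean, difference)
    coordinates are returned for plotting.
    """
    y = np.asarray(truth, float)
    p = np.asarray(predictions, float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    diff = p - y
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "mean_difference": mean_diff,
        "lower_limit": mean_diff - 1.96 * sd,
        "upper_limit": mean_diff + 1.96 * sd,
        "coordinates": pd.DataFrame({"mean": (y + p) / 2.0, "difference": diff}),
    }


# ---------------------------------------------------------------------------
# delta-quantile labelling
# ---------------------------------------------------------------------------

@dataclass
class DeltaLabels:
    """Binary direction/magnitude-of-change outcome for one quantile design."""

    deltas: pd.Series  # current - future VO2max, indexed by participant_id
    lower_q: float
    upper_q: float
    lower_threshold: float
    upper_threshold: float
    labels: pd.Series  # 0/1, defined on selected ids only

    @property
    def selected_ids(self) -> list[str]:
        return list(self.labels.index)


def make_delta_labels(deltas: pd.Series, lower_q: float, upper_q: float,
                      train_ids: Optional[Sequence[str]] = None) -> DeltaLabels:
    """Label the tails of the fitness-change distribution.

    Thresholds are the ``lower_q``/``upper_q`` quantiles of the
    *training* portion only (all ids when ``train_ids`` is omitted).
    Ids with delta <= lower threshold become class 0, >= upper threshold
    class 1, everything between is dropped; the 50/50 design
    (``lower_q == upper_q == 0.5``) keeps everyone, splitting at the
    median with ties to class 0.  When ties leave the tails unequal,
    the larger tail is trimmed from the threshold inward, ordering by
    value then participant id, so class sizes differ by at most one.
    """
    if not isinstance(deltas, pd.Series):
        raise TypeError("deltas must be a pandas Series indexed by participant id")
    median_design = lower_q == upper_q == 0.5
    if not median_design and not (0.0 < lower_q <= 0.5 <= upper_q < 1.0
                                  and lower_q < upper_q):
        raise ValueError("need 0 < lower_q <= 0.5 <= upper_q < 1 (or both 0.5)")
    train = deltas if train_ids is None else deltas.loc[list(train_ids)]
    lower_thr = float(np.quantile(train.to_numpy(float), lower_q))
    upper_thr = float(np.quantile(train.to_numpy(float), upper_q))

    if median_design:
        labels = (deltas > lower_thr).astype(int)
        if labels.nunique() < 2:
            raise ValueError("median split produced a single class")
        return DeltaLabels(deltas, lower_q, upper_q, lower_thr, lower_thr, labels)

    low_tail = deltas[deltas <= lower_thr]
    high_tail = deltas[deltas >= upper_thr]
    if low_tail.empty or high_tail.empty:
        raise ValueError("too few values to form both tail classes")
    k = min(len(low_tail), len(high_tail))
    # most extreme first; ties broken by participant id
    low_sorted = sorted(low_tail.items(), key=lambda kv: (kv[1], kv[0]))
    high_sorted = sorted(high_tail.items(), key=lambda kv: (-kv[1], kv[0]))
    keep0 = [pid for pid, _ in low_sorted[:k]]
    keep1 = [pid for pid, _ in high_sorted[:k]]
    labels = pd.concat([
        pd.Series(0, index=pd.Index(keep0, name=deltas.index.name)),
        pd.Series(1, index=pd.Index(keep1, name=deltas.index.name)),
    ])
    labels = labels.loc[[i for i in deltas.index if i in set(labels.index)]]
    return DeltaLabels(deltas, lower_q, upper_q, lower_thr, upper_thr, labels)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Metric values with bootstrap CIs for one task/model/subgroup."""

    task: str
    model: str
    subgroup: str
    n: int
    metrics: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (point, lo, hi) in self.metrics.items():
            if not (lo <= point <= hi) and np.isfinite([point, lo, hi]).all():
                raise ValueError(f"{name}: CI ({lo}, {hi}) does not bracket {point}")

    def to_json_obj(self) -> dict:
        return {
            "task": self.task,
            "model": self.model,
            "subgroup": self.subgroup,
            "n": self.n,
            "metrics": {k: list(v) for k, v in self.metrics.items()},
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "EvaluationReport":
        return cls(task=obj["task"], model=obj["model"], subgroup=obj["subgroup"],
                   n=obj["n"],
                   metrics={k: tuple(v) for k, v in obj["metrics"].items()})


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"task": r.task, "model": r.model, "subgroup": r.subgroup, "n": r.n}
        for name, (point, lo, hi) in r.metrics.items():
            row[name] = point
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def save_reports(reports: Sequence[EvaluationReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_json_obj() for r in reports], fh, indent=1)


def load_reports(path) -> list[EvaluationReport]:
    with open(path) as fh:
        return [EvaluationReport.from_json_obj(o) for o in json.load(fh)]


def subgroup_sensitivity(truth: pd.Series, predictions: pd.Series,
                         covariates: pd.DataFrame, grouping: str,
                         task: str = "task1_current", model: str = "dense",
                         n_boot: int = 500, seed: int = 0) -> list[EvaluationReport]:
    """Per-subgroup metric suite with bootstrap CIs.

    Continuous groupings split at the test-set median, with the median
    value assigned to the first (<=) group; ``sex`` splits on category.
    Empty subgroups are omitted with a warning.
    """
    if grouping not in SUBGROUP_VARIABLES:
        raise ValueError(f"grouping must be one of {SUBGROUP_VARIABLES}")
    ids = truth.index
    values = covariates.loc[ids, grouping]
    if grouping == "sex":
        groups = [(f"sex={level}", values == level) for level in ("female", "male")]
    else:
        med = float(values.median())
        groups = [(f"{grouping}<={med:g}", values <= med),
                  (f"{grouping}>{med:g}", values > med)]
    out = []
    for name, mask in groups:
        sub = ids[mask.to_numpy(bool)]
        if len(sub) == 0:
            warnings.warn(f"subgroup {name} is empty; row omitted")
            continue
        metrics = {}
        for metric in ("rmse", "mse", "r2", "pearson_r", "mae", "std_mae", "mape"):
            metrics[metric] = bootstrap_ci(truth.loc[sub], predictions.loc[sub],
                                           metric, n_boot=n_boot, seed=seed)
        out.append(EvaluationReport(task=task, model=model, subgroup=name,
                                    n=len(sub), metrics=metrics))
    return out


# ---------------------------------------------------------------------------
# split plans and task orchestration
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Participant-id partitions for all tasks (serialized for audit)."""

    task1_train: list[str]  # baseline-only participants
    task1_test: list[str]  # longitudinal participants
    task2_train: list[str]  # 80% of the longitudinal set
    task2_test: list[str]  # held-out 20%
    seed: int = 0

    def __post_init__(self):
        if set(self.task1_train) & set(self.task1_test):
            raise ValueError("task1 train and test overlap")
        longitudinal = set(self.task1_test)
        if set(self.task2_train) | set(self.task2_test) != longitudinal \
                or set(self.task2_train) & set(self.task2_test):
            raise ValueError("task2 must partition the longitudinal set")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        return cls(**json.loads(text))


def build_split_plan(baseline_ids: Sequence[str], longitudinal_ids: Sequence[str],
                     seed: int = 0, test_fraction: float = 0.2) -> SplitPlan:
    """Baseline-only -> Task-1 train; longitudinal -> Task-1 test and the
    re-randomized 80/20 Task-2 partition."""
    longitudinal = sorted(longitudinal_ids)
    baseline_only = sorted(set(baseline_ids) - set(longitudinal))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(len(longitudinal))
    n_test = int(round(test_fraction * len(longitudinal)))
    test = sorted(longitudinal[i] for i in perm[:n_test])
    train = sorted(longitudinal[i] for i in perm[n_test:])
    return SplitPlan(task1_train=baseline_only, task1_test=longitudinal,
                     task2_train=train, task2_test=test, seed=seed)


@dataclass
class TaskResult:
    reports: list[EvaluationReport]
    artifacts: dict = field(default_factory=dict)


def _tag_label(tags: frozenset) -> str:
    order = {"anthro": 0, "rhr": 1, "sensors": 2}
    return "+".join(sorted(tags, key=order.get))


def _fit_and_project(features: pd.DataFrame, train_ids, tags, registry):
    sub = select_inputs(features, set(tags), registry)
    fitted = wt.fit_transforms(sub.loc[list(train_ids)])
    return fitted, wt.apply_transforms(sub, fitted)


def _regression_metrics(y, p, n_boot, seed) -> dict:
    return {m: bootstrap_ci(y, p, m, n_boot=n_boot, seed=seed)
            for m in ("r2", "pearson_r", "rmse")}


def _adapt_config(cfg: DenseNetConfig, n_train: int) -> DenseNetConfig:
    """Shrink the batch size when the validation split would be smaller
    than one batch (small training sets and tail designs)."""
    vf = cfg.validation_fraction
    n_val = int(round(vf * n_train))
    if n_val < 2:  # batch-norm needs at least two validation/batch rows
        vf = min(0.5, 2.5 / max(n_train, 1))
        n_val = int(round(vf * n_train))
    if n_val >= cfg.batch_size and vf == cfg.validation_fraction:
        return cfg
    return dataclasses.replace(cfg, validation_fraction=vf,
                               batch_size=max(2, min(cfg.batch_size, n_val)))


DELTA_DESIGNS = ((0.5, 0.5), (0.2, 0.8), (0.1, 0.9))


def run_task(task: str, bundle, plan: Optional[SplitPlan] = None,
             artifacts: Optional[dict] = None, seed: int = 0,
             n_boot: int = 500,
             dense_config: Optional[DenseNetConfig] = None) -> TaskResult:
    """Execute one evaluation design on an assembled cohort bundle.

    ``bundle`` is a :class:`wearfit.pipeline.CohortBundle`.  Task 3
    requires the ``artifacts`` of a previous Task-1 run (frozen model
    and transforms).  Returns the metric reports plus the artifacts the
    later tasks reuse.
    """
    registry = bundle.registry or default_registry()
    plan = plan or build_split_plan(bundle.baseline.index, bundle.longitudinal_ids,
                                    seed=seed)
    artifacts = dict(artifacts or {})
    feats = bundle.features_baseline
    y_current = bundle.baseline["vo2max"]
    reports: list[EvaluationReport] = []

    if task == "task1_current":
        train_ids = [i for i in plan.task1_train if i in feats.index]
        test_ids = [i for i in plan.task1_test if i in feats.index]
        ytr, yte = y_current.loc[train_ids], y_current.loc[test_ids]
        for kind, tags in TASK1_CONFIGURATIONS:
            key = f"transforms:{_tag_label(tags)}"
            if key in artifacts:
                fitted = artifacts[key]
                proj = wt.apply_transforms(
                    select_inputs(feats, set(tags), registry), fitted)
            else:
                fitted, proj = _fit_and_project(feats, train_ids, tags, registry)
            if kind == "linear":
                model = wm.fit_linear(proj.loc[train_ids], ytr, tags=tags)
            else:
                cfg = _adapt_config(dense_config or DenseNetConfig.regressor(seed=seed),
                                    len(train_ids))
                model = wm.fit_dense_regressor(
                    proj.loc[train_ids], ytr, config=cfg, tags=tags,
                    transform_fingerprint=fitted.train_fingerprint)
            pred = wm.predict(model, proj.loc[test_ids])
            label = f"{'dense' if kind.startswith('dense') else 'linear'}:{_tag_label(tags)}"
            reports.append(EvaluationReport(
                task=task, model=label, subgroup="all", n=len(test_ids),
                metrics=_regression_metrics(yte, pred, n_boot, seed)))
            artifacts[f"transforms:{_tag_label(tags)}"] = fitted
            artifacts[f"model:{label}"] = model
        # equation baseline ignores the wearable data entirely
        cov = bundle.baseline.loc[test_ids]
        eq_pred = wm.equation_vo2max(cov["age"].to_numpy(), cov["rhr"].to_numpy())
        reports.append(EvaluationReport(
            task=task, model="equation:age+rhr", subgroup="all", n=len(test_ids),
            metrics=_regression_metrics(yte, eq_pred, n_boot, seed)))
        artifacts["plan"] = plan
        return TaskResult(reports, artifacts)

    if task in ("task2_future", "task2_delta"):
        train_ids = [i for i in plan.task2_train if i in feats.index]
        test_ids = [i for i in plan.task2_test if i in feats.index]
        tags = frozenset({"anthro", "rhr", "sensors"})
        key = f"transforms:{_tag_label(tags)}"
        if key in artifacts:  # reuse the Task-1 projection (big-cohort knowledge)
            fitted = artifacts[key]
            proj = wt.apply_transforms(select_inputs(feats, set(tags), registry), fitted)
        else:
            fitted, proj = _fit_and_project(feats, train_ids, tags, registry)
        future = bundle.followup["vo2max"]
        if task == "task2_delta":
            outcomes = {"delta": y_current.loc[future.index] - future}
        else:
            outcomes = {"current": y_current, "future": future}
        cfg = _adapt_config(dense_config or DenseNetConfig.regressor(seed=seed),
                            len(train_ids))
        for name, y in outcomes.items():
            model = wm.fit_dense_regressor(
                proj.loc[train_ids], y.loc[train_ids], config=cfg, tags=tags,
                transform_fingerprint=fitted.train_fingerprint)
            pred = wm.predict(model, proj.loc[test_ids])
            reports.append(EvaluationReport(
                task=task, model=f"dense:{name}", subgroup="all", n=len(test_ids),
                metrics=_regression_metrics(y.loc[test_ids], pred, n_boot, seed)))
            artifacts[f"model:task2:{name}"] = model
        return TaskResult(reports, artifacts)

    if task == "task2_delta_binary":
        train_ids = [i for i in plan.task2_train if i in feats.index]
        test_ids = [i for i in plan.task2_test if i in feats.index]
        tags = frozenset({"anthro", "rhr", "sensors"})
        fitted, proj = _fit_and_project(feats, train_ids, tags, registry)
        deltas = (y_current.loc[bundle.followup.index]
                  - bundle.followup["vo2max"])
        for lower_q, upper_q in DELTA_DESIGNS:
            labels = make_delta_labels(deltas, lower_q, upper_q, train_ids=train_ids)
            sel_train = [i for i in train_ids if i in labels.labels.index]
            sel_test = [i for i in test_ids if i in labels.labels.index]
            cfg = dense_config or DenseNetConfig.binary(seed=seed)
            cfg = _adapt_config(cfg, len(sel_train))
            model = wm.fit_dense_binary(
                proj.loc[sel_train], labels.labels.loc[sel_train], config=cfg,
                tags=tags, transform_fingerprint=fitted.train_fingerprint)
            scores = wm.predict(model, proj.loc[sel_test])
            design = f"{int(lower_q * 100)}/{int(upper_q * 100)}"
            reports.append(EvaluationReport(
                task=task, model=f"dense_binary:{design}", subgroup="all",
                n=len(sel_test),
                metrics={"auroc": bootstrap_ci(
                    labels.labels.loc[sel_test], scores, "auroc",
                    n_boot=n_boot, seed=seed)}))
            artifacts[f"labels:{design}"] = labels
        return TaskResult(reports, artifacts)

    if task == "task3_reuse":
        tags = frozenset({"anthro", "rhr", "sensors"})
        model = artifacts.get(f"model:dense:{_tag_label(tags)}")
        fitted = artifacts.get(f"transforms:{_tag_label(tags)}")
        if model is None or fitted is None:
            raise ValueError("task3_reuse needs the Task-1 dense model and "
                             "transforms in `artifacts`")
        if bundle.features_followup is None:
            raise ValueError("bundle has no follow-up sensor features")
        ids = [i for i in plan.task1_test
               if i in bundle.features_followup.index and i in feats.index]
        dropped = len(plan.task1_test) - len(ids)
        if dropped:
            logger.info("task3_reuse: %d participants lack follow-up traces", dropped)
        sub = select_inputs(feats.loc[ids], set(tags), registry)
        sub_fu = select_inputs(bundle.features_followup.loc[ids], set(tags), registry)
        pred_current = pd.Series(
            wm.predict(model, wt.apply_transforms(sub, fitted)), index=ids)
        pred_future = pd.Series(
            wm.predict(model, wt.apply_transforms(sub_fu, fitted)), index=ids)
        true_current = y_current.loc[ids]
        true_future = bundle.followup.loc[ids, "vo2max"]
        pred_delta = pred_current - pred_future
        true_delta = true_current - true_future
        rows = [
            ("current", true_current, pred_current),
            ("future", true_future, pred_future),
            ("delta", true_delta, pred_delta),
        ]
        for name, y, p in rows:
            reports.append(EvaluationReport(
                task=task, model=f"reused_dense:{name}", subgroup="all", n=len(ids),
                metrics={"pearson_r": bootstrap_ci(y, p, "pearson_r",
                                                   n_boot=n_boot, seed=seed)}))
        artifacts["task3_predictions"] = pd.DataFrame({
            "pred_current": pred_current, "pred_future": pred_future,
            "true_current": true_current, "true_future": true_future,
        })
        return TaskResult(reports, artifacts)

    raise ValueError(f"unknown task {task!r}")
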