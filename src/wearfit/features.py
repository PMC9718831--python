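"""Fixed-length feature vectors from cleaned participant weeks.

The default registry has 68 named features:

* 8 summary statistics (mean, min, max, sd, p25, p50, p75, least-squares
  slope) for each of 5 sensor series (acc_raw, hr, hrv, enmo, mets) = 40
* cyclical month-of-year encoding (sin, cos) = 2
* anthropometrics (age, sex, weight, bmi, height) = 5
* resting heart rate = 1
* an activity-volume block (per-class total/daily minutes, MVPA bouts,
  wear hours, wear-time fractions) = 20

Features carry one of three tags — ``anthro``, ``rhr``, ``sensors`` —
so every model-input configuration (anthropometrics only, plus RHR,
plus full sensors) is a tag union.  The registry is data-driven: users
can register their own feature definitions without touching this
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from wearfit.cohort import MINUTES_PER_DAY, ParticipantRecord, SensorTrace

SERIES_NAMES = ("acc_raw", "hr", "hrv", "enmo", "mets")
STAT_NAMES = ("mean", "min", "max", "sd", "p25", "p50", "p75", "slope")
TAGS = ("anthro", "rhr", "sensors")

#: Minimum run length (minutes) for an MVPA bout.
MVPA_BOUT_MINUTES = 10


def encode_month(first_timestamp) -> tuple[float, float]:
    """Month of year as coordinates on the unit circle.

    ``(sin(2*pi*t/12), cos(2*pi*t/12))`` for month ``t`` of the *first*
    sample, so adjacent calendar months — including December/January —
    are always one-twelfth of the circle apart.
    """
    month = pd.Timestamp(first_timestamp).month
    angle = 2.0 * np.pi * month / 12.0
    return float(np.sin(angle)), float(np.cos(angle))


def summarize_series(values: Sequence[float]) -> dict[str, float]:
    """Eight distribution summaries of a wear-time sensor series.

    The slope is the least-squares slope of value against wear-time
    position (0, 1, 2, ... per retained minute).  Requires at least two
    non-missing values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("summarize_series needs at least 2 non-missing values")
    idx = np.arange(arr.size, dtype=float)
    idx_c = idx - idx.mean()
    slope = float(idx_c @ (arr - arr.mean()) / (idx_c @ idx_c))
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "sd": float(arr.std()),
        "p25": float(np.percentile(arr, 25)),
        "p50": float(np.percentile(arr, 50)),
        "p75": float(np.percentile(arr, 75)),
        "slope": slope,
    }


@dataclass(frozen=True)
class FeatureDef:
    name: str
    tag: str
    compute: Callable[[dict], float]


class FeatureRegistry:
    """Ordered, tagged feature definitions."""

    def __init__(self, features: Iterable[FeatureDef]):
        self.features = list(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        bad = {f.tag for f in self.features} - set(TAGS)
        if bad:
            raise ValueError(f"unknown feature tags {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def restrict(self, tags: set[str]) -> "FeatureRegistry":
        if not tags:
            raise ValueError("tag set must be non-empty")
        bad = set(tags) - set(TAGS)
        if bad:
            raise ValueError(f"unknown tags {sorted(bad)}")
        return FeatureRegistry([f for f in self.features if f.tag in tags])

    def names_for(self, tags: set[str]) -> list[str]:
        return self.restrict(tags).names

    def to_json_obj(self) -> list[dict]:
        return [{"name": f.name, "tag": f.tag} for f in self.features]


def _series_stat(series: str, stat: str) -> FeatureDef:
    def compute(ctx: dict) -> float:
        return ctx["series_stats"][series][stat]

    return FeatureDef(name=f"{series}_{stat}", tag="sensors", compute=compute)


def _activity_block(mvpa_includes_vpa: bool) -> list[FeatureDef]:
    classes = ("sedentary", "light", "mvpa", "vpa")

    def class_minutes(ctx: dict, cls: str) -> np.ndarray:
        mets = ctx["mets"]
        if cls == "sedentary":
            mask = mets <= 1.5
        elif cls == "light":
            mask = (mets > 1.5) & (mets < 3.0)
        elif cls == "mvpa":
            mask = mets >= 3.0 if mvpa_includes_vpa else (mets >= 3.0) & (mets <= 6.0)
        else:
            mask = mets > 6.0
        return mask

    defs: list[FeatureDef] = []
    for cls in classes:
        defs.append(FeatureDef(
            f"{cls}_total_min", "sensors",
            lambda ctx, c=cls: float(class_minutes(ctx, c).sum())))
    for cls in classes:
        defs.append(FeatureDef(
            f"{cls}_daily_mean_min", "sensors",
            lambda ctx, c=cls: float(np.mean(
                [m.sum() for m in _by_day(ctx, class_minutes(ctx, c))]))))
    for cls in classes:
        defs.append(FeatureDef(
            f"{cls}_daily_max_min", "sensors",
            lambda ctx, c=cls: float(np.max(
                [m.sum() for m in _by_day(ctx, class_minutes(ctx, c))]))))
    defs += [
        FeatureDef("mvpa_bout_count", "sensors",
                   lambda ctx: float(len(ctx["mvpa_bouts"]))),
        FeatureDef("mvpa_bout_mean_min", "sensors",
                   lambda ctx: float(np.mean(ctx["mvpa_bouts"])) if ctx["mvpa_bouts"] else 0.0),
        FeatureDef("mvpa_bout_max_min", "sensors",
                   lambda ctx: float(np.max(ctx["mvpa_bouts"])) if ctx["mvpa_bouts"] else 0.0),
        FeatureDef("wear_hours_total", "sensors",
                   lambda ctx: float(ctx["wear"].sum()) / 60.0),
        FeatureDef("wear_hours_daily_mean", "sensors",
                   lambda ctx: float(np.mean(
                       [w.sum() for w in _by_day(ctx, ctx["wear"][ctx["wear"]])])) / 60.0
                   if ctx["wear"].any() else 0.0),
        FeatureDef("frac_wear_sedentary", "sensors",
                   lambda ctx: float(class_minutes(ctx, "sedentary").mean())),
        FeatureDef("frac_wear_mvpa", "sensors",
                   lambda ctx: float(class_minutes(ctx, "mvpa").mean())),
        FeatureDef("frac_wear_vpa", "sensors",
                   lambda ctx: float(class_minutes(ctx, "vpa").mean())),
    ]
    return defs


def _by_day(ctx: dict, mask: np.ndarray) -> list[np.ndarray]:
    """Split a wear-minute mask back into calendar days."""
    days = ctx["day_index"]
    return [mask[days == d] for d in range(int(days.max()) + 1)] if mask.size else [mask]


def default_registry(mvpa_includes_vpa: bool = True) -> FeatureRegistry:
    """The canonical 68-entry feature registry.

    ``mvpa_includes_vpa`` controls whether MVPA minutes count every
    minute at >= 3 METs (the default) or only the 3-6 MET band; the
    moderate-to-vigorous definition is ambiguous in common usage, so
    both are supported.
    """
    defs: list[FeatureDef] = []
    for series in SERIES_NAMES:
        for stat in STAT_NAMES:
            defs.append(_series_stat(series, stat))
    defs.append(FeatureDef("month_sin", "sensors", lambda ctx: ctx["month_sin"]))
    defs.append(FeatureDef("month_cos", "sensors", lambda ctx: ctx["month_cos"]))
    defs.append(FeatureDef("age", "anthro", lambda ctx: ctx["record"].age))
    defs.append(FeatureDef("sex", "anthro",
                           lambda ctx: 1.0 if ctx["record"].sex == "male" else 0.0))
    defs.append(FeatureDef("weight", "anthro", lambda ctx: ctx["record"].weight))
    defs.append(FeatureDef("bmi", "anthro", lambda ctx: ctx["record"].bmi))
    defs.append(FeatureDef("height", "anthro", lambda ctx: ctx["record"].height))
    defs.append(FeatureDef("rhr", "rhr", lambda ctx: ctx["record"].rhr))
    defs += _activity_block(mvpa_includes_vpa)
    registry = FeatureRegistry(defs)
    assert len(registry) == 68
    return registry


def _mvpa_bout_lengths(mets: np.ndarray, min_minutes: int = MVPA_BOUT_MINUTES) -> list[int]:
    """Lengths of maximal runs of consecutive wear minutes at >= 3 METs."""
    mask = (mets >= 3.0).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    return [int(b - a) for a, b in zip(edges[::2], edges[1::2]) if b - a >= min_minutes]


def build_feature_vector(participant: ParticipantRecord, trace: SensorTrace,
                         registry: FeatureRegistry | None = None) -> pd.Series:
    """One participant week -> one named feature vector.

    All sensor statistics are computed over wear minutes only (the
    trace must already carry ``wear``, ``enmo`` and ``mets`` columns
    from processing); order and length follow the registry.
    """
    registry = registry or default_registry()
    data = trace.data.sort_index()
    for col in ("wear", "enmo", "mets"):
        if col not in data.columns:
            raise ValueError(f"trace for {participant.participant_id} not processed "
                             f"(missing {col!r} channel)")
    wear = data["wear"].to_numpy(bool)
    if wear.sum() < 2:
        raise ValueError(f"participant {participant.participant_id} has no usable "
                         f"wear data")
    series_stats = {}
    for name in SERIES_NAMES:
        values = data.loc[wear, name].to_numpy(float)
        values = values[np.isfinite(values)]
        if values.size < 2:
            raise ValueError(
                f"participant {participant.participant_id} ineligible: series "
                f"{name!r} has fewer than 2 non-missing wear-time values")
        series_stats[name] = summarize_series(values)
    month_sin, month_cos = encode_month(trace.start)
    mets_wear = data.loc[wear, "mets"].to_numpy(float)
    ctx = {
        "record": participant,
        "series_stats": series_stats,
        "month_sin": month_sin,
        "month_cos": month_cos,
        "mets": mets_wear,
        "wear": wear,
        "day_index": (data.index.to_numpy()[wear] // MINUTES_PER_DAY),
        "mvpa_bouts": _mvpa_bout_lengths(mets_wear),
    }
    values = [f.compute(ctx) for f in registry.features]
    vec = pd.Series(values, index=registry.names, name=participant.participant_id,
                    dtype=float)
    if vec.isna().any():
        bad = list(vec.index[vec.isna()])
        raise ValueError(f"feature extraction produced missing values: {bad}")
    return vec


def build_feature_matrix(participants: Sequence[ParticipantRecord],
                         traces: dict[str, SensorTrace],
                         registry: FeatureRegistry | None = None) -> pd.DataFrame:
    """Stack per-participant vectors into a (participants x features) table."""
    registry = registry or default_registry()
    rows = [build_feature_vector(p, traces[p.participant_id], registry)
            for p in participants]
    return pd.DataFrame(rows)


def select_inputs(matrix: pd.DataFrame, tags: set[str],
                  registry: FeatureRegistry | None = None) -> pd.DataFrame:
    """Column subset of a feature matrix for one model-input configuration."""
    registry = registry or default_registry()
    cols = registry.names_for(set(tags))
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing registry columns {missing}")
    return matrix[cols]
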