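"""Cleaning of raw minute-level sensor traces.

Order of operations for a participant week: heart-rate noise filtering,
non-wear detection (prolonged zero movement together with absent or
non-physiological heart rate), derivation of the ENMO and MET channels,
intensity classification, wear-time eligibility, and free-living
resting-heart-rate estimation from nocturnal sleep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wearfit.cohort import JOULES_PER_MET, MINUTES_PER_DAY, SensorTrace

#: Intensities below this (J/min/kg) count as "no movement" — sensor noise floor.
ZERO_MOVEMENT_TOLERANCE = 1.0
#: Physiological heart-rate band (beats/min); values outside become missing.
HR_BAND = (30.0, 220.0)
#: Minute-to-minute jump (beats/min) that marks an isolated HR spike.
HR_SPIKE_JUMP = 60.0
#: ENMO (milli-g) is synthesized as a fixed monotone rescaling of acc_raw.
ENMO_PER_ACC = 0.85

INTENSITY_CLASSES = ("sedentary", "light", "mvpa", "vpa")


@dataclass
class WearSummary:
    """Wear-time accounting for one participant week."""

    total_wear_hours: float
    eligible: bool
    nonwear_runs: list[tuple[int, int]] = field(default_factory=list)  # (start, length)

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_wear_hours": self.total_wear_hours,
                "eligible": self.eligible,
                "nonwear_runs": [list(r) for r in self.nonwear_runs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WearSummary":
        obj = json.loads(text)
        return cls(
            total_wear_hours=obj["total_wear_hours"],
            eligible=obj["eligible"],
            nonwear_runs=[tuple(r) for r in obj["nonwear_runs"]],
        )


def to_mets(intensity) -> np.ndarray | float:
    """Convert activity intensity (J/min/kg) to METs, 1 MET = 71 J/min/kg."""
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensity must be non-negative")
    out = arr / JOULES_PER_MET
    return float(out) if np.isscalar(intensity) or out.ndim == 0 else out


def classify_intensity(mets) -> np.ndarray | str:
    """Classify METs into sedentary (<=1.5), light, MVPA (3-6), VPA (>6).

    The bands partition [0, inf): the interval (1.5, 3) is labelled
    "light" so every wear minute receives exactly one class.
    """
    arr = np.asarray(mets, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mets must be non-negative")
    out = np.full(arr.shape, "sedentary", dtype=object)
    out[(arr > 1.5) & (arr < 3.0)] = "light"
    out[(arr >= 3.0) & (arr <= 6.0)] = "mvpa"
    out[arr > 6.0] = "vpa"
    if np.isscalar(mets) or arr.ndim == 0:
        return str(out.item() if arr.ndim == 0 else out)
    return out.astype(str)


def filter_hr(trace: SensorTrace,
              band: tuple[float, float] = HR_BAND,
              spike_jump: float = HR_SPIKE_JUMP) -> SensorTrace:
    """Set implausible heart-rate samples to missing.

    Removes values outside the physiological ``band`` and isolated
    single-minute spikes that jump more than ``spike_jump`` beats/min
    against *both* neighbours.  Idempotent: a second pass changes
    nothing because removed spikes no longer have two finite neighbours.
    """
    out = trace.copy()
    hr = out.data["hr"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = np.isfinite(hr) & ((hr < band[0]) | (hr > band[1]))
    if len(hr) >= 3:
        prev, nxt = hr[:-2], hr[2:]
        mid = hr[1:-1]
        with np.errstate(invalid="ignore"):
            spike = (
                np.isfinite(mid) & np.isfinite(prev) & np.isfinite(nxt)
                & (np.abs(mid - prev) > spike_jump)
                & (np.abs(mid - nxt) > spike_jump)
            )
        bad[1:-1] |= spike
    hr[bad] = np.nan
    out.data["hr"] = hr
    return out


def detect_nonwear(trace: SensorTrace, min_gap_minutes: int = 90,
                   zero_movement_tolerance: float = ZERO_MOVEMENT_TOLERANCE,
                   band: tuple[float, float] = HR_BAND,
                   eligibility_hours: float = 72.0) -> WearSummary:
    """Flag extended no-movement, no-heart-rate runs as non-wear.

    A maximal run of minutes is flagged iff it is strictly longer than
    ``min_gap_minutes``, movement stays below the zero-movement
    tolerance throughout, and heart rate is missing or outside the
    physiological band throughout.  The trace's ``wear`` column is
    updated in place (non-wear minutes are excluded from every
    downstream statistic).
    """
    n = trace.n_minutes
    if n == 0:
        trace.data["wear"] = pd.Series(dtype=bool)
        return WearSummary(total_wear_hours=0.0, eligible=False, nonwear_runs=[])
    intensity = trace.data["intensity"].to_numpy(float)
    hr = trace.data["hr"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        candidate = (intensity < zero_movement_tolerance) & (
            ~np.isfinite(hr) | (hr < band[0]) | (hr > band[1])
        )
    wear = np.ones(n, dtype=bool)
    runs: list[tuple[int, int]] = []
    # maximal-run scan
    edges = np.flatnonzero(np.diff(np.concatenate(([0], candidate.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a > min_gap_minutes:
            runs.append((int(a), int(b - a)))
            wear[a:b] = False
    trace.data["wear"] = wear
    hours = float(wear.sum()) / 60.0
    return WearSummary(
        total_wear_hours=hours,
        eligible=hours >= eligibility_hours,
        nonwear_runs=runs,
    )


def wear_eligibility(summary: WearSummary, min_hours: float = 72.0) -> bool:
    """Eligible iff at least ``min_hours`` of wear (3 full days by default)."""
    return summary.total_wear_hours >= min_hours


def derive_rhr(trace: SensorTrace, supine_rhr: float | None = None,
               window_minutes: int = 30) -> float:
    """Free-living resting heart rate.

    Sleeping HR is the mean over the lowest-mean contiguous 30-minute
    window inside the nocturnal low-activity period (23:30-06:30, wear
    minutes with observed HR only).  The result is the average of the
    sleeping HR and the supine clinic measurement when one is supplied.
    Raises ``ValueError`` when no usable nocturnal window exists and no
    supine value is available to fall back on.
    """
    mod = trace.minute_of_day
    nocturnal = (mod >= 1410) | (mod < 390)
    hr = trace.data["hr"].to_numpy(float)
    wear = trace.data["wear"].to_numpy(bool) if "wear" in trace.data else np.ones(len(hr), bool)
    usable = nocturnal & wear & np.isfinite(hr)

    best = np.inf
    # contiguous usable segments, then every in-segment window of the set size
    edges = np.flatnonzero(np.diff(np.concatenate(([0], usable.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < window_minutes:
            continue
        seg = hr[a:b]
        csum = np.concatenate(([0.0], np.cumsum(seg)))
        means = (csum[window_minutes:] - csum[:-window_minutes]) / window_minutes
        m = means.min()
        if m < best:
            best = m
    if not np.isfinite(best):
        if supine_rhr is not None:
            return float(supine_rhr)
        raise ValueError("no nocturnal wear data; sleeping heart rate unavailable")
    sleeping = float(best)
    if supine_rhr is None:
        return sleeping
    return (sleeping + float(supine_rhr)) / 2.0


def process_trace(trace: SensorTrace, min_gap_minutes: int = 90,
                  eligibility_hours: float = 72.0) -> tuple[SensorTrace, WearSummary]:
    """Full cleaning pass: HR filter, non-wear, derived ENMO/MET channels."""
    out = filter_hr(trace)
    out.nonwear_true = trace.nonwear_true
    summary = detect_nonwear(out, min_gap_minutes=min_gap_minutes,
                             eligibility_hours=eligibility_hours)
    out.data["enmo"] = ENMO_PER_ACC * out.data["acc_raw"].to_numpy(float)
    out.data["mets"] = to_mets(out.data["intensity"].to_numpy(float))
    return out, summary
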