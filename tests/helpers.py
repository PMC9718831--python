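"""Shared test utilities: hand-built traces and independent oracles.

Every oracle here is written as a direct, naive transcription of the
relevant definition (explicit loops, closed-form formulas, O(n^2)
scans) so it shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from wearfit.cohort import SensorTrace


def make_trace(intensity, hr, hrv=None, acc=None, start="2015-03-02",
               participant_id="T0000") -> SensorTrace:
    intensity = np.asarray(intensity, float)
    n = len(intensity)
    hr = np.asarray(hr, float)
    data = pd.DataFrame(
        {
            "acc_raw": np.asarray(acc, float) if acc is not None else 0.5 * intensity,
            "intensity": intensity,
            "hr": hr,
            "hrv": np.asarray(hrv, float) if hrv is not None else np.full(n, 40.0),
        },
        index=pd.RangeIndex(n, name="minute_index"),
    )
    return SensorTrace(participant_id, pd.Timestamp(start), data)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_nonwear_runs(intensity, hr, min_gap=90, tol=1.0, band=(30.0, 220.0)):
    """Naive maximal-run scan for qualifying non-wear periods."""
    n = len(intensity)

    def bad(j):
        no_move = intensity[j] < tol
        hr_bad = np.isnan(hr[j]) or hr[j] < band[0] or hr[j] > band[1]
        return no_move and hr_bad

    runs, i = [], 0
    while i < n:
        if bad(i):
            j = i
            while j < n and bad(j):
                j += 1
            if j - i > min_gap:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def brute_summary(values):
    """Direct-formula summaries, independent of the package implementation."""
    arr = np.sort(np.asarray(values, float))
    n = arr.size

    def quantile(q):
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return arr[lo] + (h - lo) * (arr[hi] - arr[lo])

    x = np.arange(n, dtype=float)
    vals = np.asarray(values, float)
    mean = float(np.sum(vals) / n)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (vals - mean)) / sxx)
    return {
        "mean": mean,
        "min": float(arr[0]),
        "max": float(arr[-1]),
        "sd": float(np.sqrt(np.sum((vals - mean) ** 2) / n)),
        "p25": float(quantile(0.25)),
        "p50": float(quantile(0.50)),
        "p75": float(quantile(0.75)),
        "slope": slope,
    }


def brute_auroc(labels, scores):
    """Exhaustive pairwise positive-vs-negative comparison."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_knn(ids, vectors, query_id, k):
    """Exhaustive Euclidean neighbour search with (distance, id) ordering."""
    qi = ids.index(query_id)
    scored = []
    for i, pid in enumerate(ids):
        if i == qi:
            continue
        d = float(np.sqrt(np.sum((vectors[i] - vectors[qi]) ** 2)))
        scored.append((d, pid))
    scored.sort()
    return [pid for _, pid in scored[:k]], [d for d, _ in scored[:k]]
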