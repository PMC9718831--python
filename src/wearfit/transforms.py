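"""Train-set-fitted standardization and PCA denoising.

The scaler (per-feature mean/sd) and the PCA basis are fitted on
training data only, serialized, and applied frozen everywhere else —
the same fitted transforms are reused across every downstream task so
no test-set statistic can leak into them.  Retained components are the
smallest set whose cumulative explained variance reaches the threshold
(99.99% by default, which denoises while keeping essentially all
structure).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


def ids_fingerprint(ids: Sequence[str]) -> str:
    """Stable digest of a participant-id set (order-insensitive)."""
    joined = ",".join(sorted(str(i) for i in ids))
    return hashlib.sha256(joined.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FittedTransforms:
    """Immutable scaler + PCA parameters fitted on one training set."""

    columns: tuple[str, ...]
    mean: np.ndarray  # (F,)
    scale: np.ndarray  # (F,), 1.0 for zero-variance features
    components: np.ndarray  # (k, F), rows are retained components
    explained_variance_ratio: np.ndarray  # (F,), full spectrum
    variance_threshold: float
    train_fingerprint: str

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def __post_init__(self):
        for arr in (self.mean, self.scale, self.components,
                    self.explained_variance_ratio):
            arr.setflags(write=False)


def fit_transforms(train_matrix: pd.DataFrame,
                   variance_threshold: float = 0.9999) -> FittedTransforms:
    """Fit standard scaling then PCA on the training matrix.

    The retained component count is the smallest ``k`` with cumulative
    explained variance >= ``variance_threshold`` (inclusive).  PCA uses
    the exact full decomposition and a fixed sign convention (largest-
    magnitude loading of each component positive) so serialized
    transforms are platform-stable.
    """
    if not isinstance(train_matrix, pd.DataFrame):
        train_matrix = pd.DataFrame(train_matrix)
    # canonical layout: reduction order (hence the fitted parameters) must
    # not depend on how the caller's frame happens to sit in memory
    X = np.ascontiguousarray(train_matrix.to_numpy(float))
    if X.shape[0] < 2:
        raise ValueError("fit_transforms needs at least 2 training rows")
    if not np.isfinite(X).all():
        raise ValueError("training matrix contains missing values")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / scale

    pca = PCA(svd_solver="full", random_state=0)
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(evr))
    components = pca.components_[:k].copy()
    # sign convention: largest-|loading| entry of each component positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return FittedTransforms(
        columns=tuple(train_matrix.columns.astype(str)),
        mean=mean,
        scale=scale,
        components=components,
        explained_variance_ratio=evr.copy(),
        variance_threshold=float(variance_threshold),
        train_fingerprint=ids_fingerprint(train_matrix.index.astype(str)),
    )


def apply_transforms(matrix: pd.DataFrame, fitted: FittedTransforms) -> pd.DataFrame:
    """Standardize with the *training* mean/sd and project on the basis.

    Never refits: the fitted parameters are read-only and identical
    before and after every call.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(matrix, columns=list(fitted.columns))
    got = tuple(matrix.columns.astype(str))
    if got != fitted.columns:
        extra = [c for c in got if c not in fitted.columns]
        missing = [c for c in fitted.columns if c not in got]
        raise ValueError(
            f"column mismatch with fitted transforms: missing {missing}, "
            f"unexpected {extra}")
    X = matrix.to_numpy(float)
    Z = (X - fitted.mean) / fitted.scale
    proj = Z @ fitted.components.T
    cols = [f"pc{i + 1}" for i in range(fitted.n_components)]
    return pd.DataFrame(proj, index=matrix.index, columns=cols)


def scale_only(matrix: pd.DataFrame, fitted: FittedTransforms) -> pd.DataFrame:
    """Standardized (but unprojected) features, e.g. for 'original space'
    distance computations."""
    got = tuple(matrix.columns.astype(str))
    if got != fitted.columns:
        raise ValueError("column mismatch with fitted transforms")
    Z = (matrix.to_numpy(float) - fitted.mean) / fitted.scale
    return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# persistence: JSON header + binary-free CSV component matrix
# ---------------------------------------------------------------------------

def save_transforms(fitted: FittedTransforms, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "columns": list(fitted.columns),
        "mean": fitted.mean.tolist(),
        "scale": fitted.scale.tolist(),
        "explained_variance_ratio": fitted.explained_variance_ratio.tolist(),
        "variance_threshold": fitted.variance_threshold,
        "n_components": fitted.n_components,
        "train_fingerprint": fitted.train_fingerprint,
    }
    (directory / "transforms.json").write_text(json.dumps(header, indent=1))
    pd.DataFrame(fitted.components, columns=list(fitted.columns)).to_csv(
        directory / "components.csv", index=False, float_format="%.17g")


def load_transforms(directory) -> FittedTransforms:
    directory = Path(directory)
    header = json.loads((directory / "transforms.json").read_text())
    comp = pd.read_csv(directory / "components.csv",
                       float_precision="round_trip").to_numpy(float)
    return FittedTransforms(
        columns=tuple(header["columns"]),
        mean=np.asarray(header["mean"], float),
        scale=np.asarray(header["scale"], float),
        components=comp,
        explained_variance_ratio=np.asarray(header["explained_variance_ratio"], float),
        variance_threshold=header["variance_threshold"],
        train_fingerprint=header["train_fingerprint"],
    )
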