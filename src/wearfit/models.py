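"""Estimator families: published equation, linear regression, dense nets.

Four model kinds share one ``TrainedModel`` wrapper: the non-exercise
heart-rate-ratio equation baseline, ordinary least squares, the dense
regression network and the dense binary classifier.  Dense kinds
additionally expose the 128-dimensional penultimate-layer embedding
used for latent-space subtyping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from wearfit._dense import DenseNet, DenseNetConfig

MODEL_KINDS = ("equation", "linear", "dense_regressor", "dense_binary")


def equation_vo2max(age: float, rhr: float, body_mass: Optional[float] = None,
                    mass_multiplied: bool = False):
    """Non-exercise VO2max from the heart-rate-ratio method.

    ``hrmax = 208 - 0.7 * age`` (age-predicted maximum) and the default
    per-kg estimate is ``15.0 * hrmax / rhr`` (mL O2/min/kg).  The
    literal mass-multiplied variant ``15.0 * body_mass * hrmax / rhr``
    is available behind ``mass_multiplied=True``; note it returns
    absolute mL O2/min rather than the per-kg units used everywhere
    else, which is why the per-kg form is the default.
    """
    age = np.asarray(age, float)
    rhr = np.asarray(rhr, float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    if np.any(rhr <= 0):
        raise ValueError("resting heart rate must be positive")
    hrmax = 208.0 - 0.7 * age
    est = 15.0 * hrmax / rhr
    if mass_multiplied:
        if body_mass is None:
            raise ValueError("body_mass required for the mass-multiplied form")
        est = est * np.asarray(body_mass, float)
    return float(est) if est.ndim == 0 else est


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed to refuse bad inputs."""

    kind: str
    estimator: object
    feature_names: tuple[str, ...]
    tags: frozenset = frozenset()
    seed: int = 0
    transform_fingerprint: Optional[str] = None
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


def _as_matrix(features, feature_names: tuple[str, ...] | None = None):
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns.astype(str))
        if feature_names is not None and names != feature_names:
            raise ValueError(
                f"feature columns {list(names)} do not match the training "
                f"columns {list(feature_names)}")
        return features.to_numpy(float), names
    X = np.asarray(features, float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width "
            f"{len(feature_names)}")
    return X, feature_names or tuple(f"x{i}" for i in range(X.shape[1]))


def fit_linear(features, outcome, tags=frozenset()) -> TrainedModel:
    """Ordinary least squares with intercept (coefficients exposed)."""
    X, names = _as_matrix(features)
    y = np.asarray(outcome, float)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least n_features + 1 rows for OLS")
    design = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    est = LinearRegression().fit(X, y)
    return TrainedModel(kind="linear", estimator=est, feature_names=names,
                        tags=frozenset(tags))


def fit_dense_regressor(features, outcome,
                        config: DenseNetConfig | None = None,
                        tags=frozenset(),
                        transform_fingerprint: Optional[str] = None) -> TrainedModel:
    """Train the dense regression network (2x128 ELU blocks, MSE)."""
    config = config or DenseNetConfig.regressor()
    if config.loss != "mse":
        raise ValueError("dense regressor must use the MSE loss")
    X, names = _as_matrix(features)
    y = np.asarray(outcome, float)
    net = DenseNet(X.shape[1], config).fit(X, y)
    return TrainedModel(kind="dense_regressor", estimator=net, feature_names=names,
                        tags=frozenset(tags), seed=config.seed,
                        transform_fingerprint=transform_fingerprint,
                        history=net.history)


def fit_dense_binary(features, labels,
                     config: DenseNetConfig | None = None,
                     tags=frozenset(),
                     transform_fingerprint: Optional[str] = None) -> TrainedModel:
    """Train the one-block sigmoid classifier on binary cross-entropy."""
    config = config or DenseNetConfig.binary()
    if config.loss != "bce":
        raise ValueError("dense binary classifier must use the BCE loss")
    X, names = _as_matrix(features)
    y = np.asarray(labels, float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    net = DenseNet(X.shape[1], config).fit(X, y)
    return TrainedModel(kind="dense_binary", estimator=net, feature_names=names,
                        tags=frozenset(tags), seed=config.seed,
                        transform_fingerprint=transform_fingerprint,
                        history=net.history)


def predict(model: TrainedModel, features) -> np.ndarray:
    """Deterministic inference; no parameter is updated by prediction."""
    X, _ = _as_matrix(features, model.feature_names)
    if model.kind == "linear":
        return model.estimator.predict(X)
    if model.kind in ("dense_regressor", "dense_binary"):
        return model.estimator.predict(X)
    raise ValueError(f"predict not defined for kind {model.kind!r}")


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (weights + manifest) as a single JSON file.

    The manifest records the feature tags, seed and the fingerprint of
    the transforms the model was trained behind, so a reloaded model can
    refuse inputs projected by mismatched transforms.
    """
    obj = {
        "kind": model.kind,
        "feature_names": list(model.feature_names),
        "tags": sorted(model.tags),
        "seed": model.seed,
        "transform_fingerprint": model.transform_fingerprint,
        "history": model.history,
    }
    if model.kind == "linear":
        obj["coef"] = model.estimator.coef_.tolist()
        obj["intercept"] = float(model.estimator.intercept_)
    elif model.kind in ("dense_regressor", "dense_binary"):
        net: DenseNet = model.estimator
        obj["config"] = dataclasses.asdict(net.config)
        obj["n_features"] = net.n_features
        obj["params"] = {k: v.tolist() for k, v in net.params.items()}
        obj["running"] = {k: v.tolist() for k, v in net.running.items()}
    else:
        raise ValueError(f"cannot serialize model kind {model.kind!r}")
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        obj = json.load(fh)
    kind = obj["kind"]
    if kind == "linear":
        est = LinearRegression()
        est.coef_ = np.asarray(obj["coef"], float)
        est.intercept_ = obj["intercept"]
    else:
        cfg = DenseNetConfig(**obj["config"])
        est = DenseNet(obj["n_features"], cfg)
        est.params = {k: np.asarray(v, float) for k, v in obj["params"].items()}
        est.running = {k: np.asarray(v, float) for k, v in obj["running"].items()}
    return TrainedModel(
        kind=kind, estimator=est, feature_names=tuple(obj["feature_names"]),
        tags=frozenset(obj["tags"]), seed=obj["seed"],
        transform_fingerprint=obj["transform_fingerprint"],
        history=obj.get("history", {}),
    )


def extract_latent(model: TrainedModel, features) -> np.ndarray:
    """Penultimate-layer embedding (n x units), dense models only."""
    if model.kind not in ("dense_regressor", "dense_binary"):
        raise ValueError("latent extraction is defined only for dense models")
    X, _ = _as_matrix(features, model.feature_names)
    return model.estimator.latent(X)
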