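"""A small, fully deterministic feed-forward network in NumPy.

Implements exactly the architecture family used throughout the
pipeline: blocks of dense -> batch-norm -> ELU -> dropout, a linear or
sigmoid single-unit head, Glorot-uniform initialization, Adam on MSE or
binary cross-entropy, a random validation split, early stopping with
best-weight restoration, and reduce-on-plateau learning-rate decay.
At these problem sizes (tens of input dimensions, 128-unit layers)
NumPy matmuls train the model in seconds, and every stochastic choice
(init, split, shuffling, dropout) comes from one seeded generator, so
identical seeds give bit-identical models.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_EPS = 1e-7


@dataclass
class DenseNetConfig:
    """Architecture and training schedule of the dense networks.

    Defaults are the regression configuration: two 128-unit hidden
    blocks, dropout 0.3, Adam at 1e-3 on MSE, batch size 32, a random
    10% validation split, early stopping after 15 non-improving epochs
    and learning-rate x0.1 on a 5-epoch validation plateau.  The binary
    classifier uses one hidden block, a sigmoid head and cross-entropy.

    ``lr_schedule`` selects between "plateau" (reduce when the
    validation loss stalls, the default) and "step" (unconditional x
    ``lr_reduce_factor`` every ``lr_reduce_patience`` epochs).
    """

    hidden_layers: int = 2
    units: int = 128
    dropout_rate: float = 0.3
    batch_norm: bool = True
    loss: str = "mse"  # "mse" | "bce"
    learning_rate: float = 1e-3
    max_epochs: int = 300
    batch_size: int = 32
    validation_fraction: float = 0.10
    early_stop_patience: int = 15
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 5
    lr_schedule: str = "plateau"  # "plateau" | "step"
    restore_best: bool = True
    seed: int = 0

    @classmethod
    def regressor(cls, **kw) -> "DenseNetConfig":
        return cls(**kw)

    @classmethod
    def binary(cls, **kw) -> "DenseNetConfig":
        kw.setdefault("hidden_layers", 1)
        kw.setdefault("loss", "bce")
        return cls(**kw)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


class DenseNet:
    """Feed-forward net; see :class:`DenseNetConfig` for the family."""

    def __init__(self, n_features: int, config: DenseNetConfig):
        self.config = config
        self.n_features = int(n_features)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self._rng = rng
        self.params: dict[str, np.ndarray] = {}
        fan_in = self.n_features
        for layer in range(config.hidden_layers):
            self.params[f"W{layer}"] = _glorot_uniform(rng, fan_in, config.units)
            self.params[f"b{layer}"] = np.zeros(config.units)
            if config.batch_norm:
                self.params[f"gamma{layer}"] = np.ones(config.units)
                self.params[f"beta{layer}"] = np.zeros(config.units)
            fan_in = config.units
        self.params["W_out"] = _glorot_uniform(rng, fan_in, 1)
        self.params["b_out"] = np.zeros(1)
        self.running: dict[str, np.ndarray] = {}
        for layer in range(config.hidden_layers):
            if config.batch_norm:
                self.running[f"mean{layer}"] = np.zeros(config.units)
                self.running[f"var{layer}"] = np.ones(config.units)
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": []}
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None):
        cfg = self.config
        cache = {"inputs": [], "z": [], "bn": [], "act": [], "drop_mask": []}
        h = X
        for layer in range(cfg.hidden_layers):
            cache["inputs"].append(h)
            z = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            cache["z"].append(z)
            if cfg.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.running[f"mean{layer}"] = (
                        _BN_MOMENTUM * self.running[f"mean{layer}"]
                        + (1 - _BN_MOMENTUM) * mu)
                    self.running[f"var{layer}"] = (
                        _BN_MOMENTUM * self.running[f"var{layer}"]
                        + (1 - _BN_MOMENTUM) * var)
                else:
                    mu = self.running[f"mean{layer}"]
                    var = self.running[f"var{layer}"]
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * inv_std
                h = self.params[f"gamma{layer}"] * zhat + self.params[f"beta{layer}"]
                cache["bn"].append((zhat, inv_std, mu))
            else:
                h = z
                cache["bn"].append(None)
            h = _elu(h)
            cache["act"].append(h)
            if training and cfg.dropout_rate > 0:
                mask = (rng.random(h.shape) >= cfg.dropout_rate)
                h = h * mask / (1.0 - cfg.dropout_rate)
                cache["drop_mask"].append(mask)
            else:
                cache["drop_mask"].append(None)
        out = h @ self.params["W_out"] + self.params["b_out"]
        cache["penultimate_input"] = h
        return out[:, 0], cache

    # -- backward --------------------------------------------------------
    def _backward(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        pred, cache = self._forward(X, training=True, rng=rng)
        m = X.shape[0]
        if cfg.loss == "mse":
            loss = float(np.mean((pred - y) ** 2))
            dz_out = (2.0 / m) * (pred - y)
        else:  # bce with logits
            p = 1.0 / (1.0 + np.exp(-pred))
            loss = float(np.mean(
                np.logaddexp(0.0, pred) - y * pred))
            dz_out = (p - y) / m
        grads = {}
        h_last = cache["penultimate_input"]
        grads["W_out"] = h_last.T @ dz_out[:, None]
        grads["b_out"] = np.array([dz_out.sum()])
        dh = dz_out[:, None] @ self.params["W_out"].T
        for layer in reversed(range(cfg.hidden_layers)):
            mask = cache["drop_mask"][layer]
            if mask is not None:
                dh = dh * mask / (1.0 - cfg.dropout_rate)
            act = cache["act"][layer]
            # d/dz of ELU: 1 where z>0 else elu(z)+1
            dpre = dh * np.where(act > 0, 1.0, act + 1.0)
            if cfg.batch_norm:
                zhat, inv_std, mu = cache["bn"][layer]
                z = cache["z"][layer]
                gamma = self.params[f"gamma{layer}"]
                grads[f"gamma{layer}"] = (dpre * zhat).sum(axis=0)
                grads[f"beta{layer}"] = dpre.sum(axis=0)
                dzhat = dpre * gamma
                mb = z.shape[0]
                dvar = (dzhat * (z - mu)).sum(axis=0) * (-0.5) * inv_std**3
                dmu = (-(dzhat.sum(axis=0)) * inv_std
                       + dvar * (-2.0 / mb) * (z - mu).sum(axis=0))
                dz = dzhat * inv_std + dvar * 2.0 * (z - mu) / mb + dmu / mb
            else:
                dz = dpre
            x_in = cache["inputs"][layer]
            grads[f"W{layer}"] = x_in.T @ dz
            grads[f"b{layer}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{layer}"].T
        return loss, grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self._adam_t += 1
        b1, b2 = 0.9, 0.999
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)

    def _eval_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred, _ = self._forward(X, training=False)
        if self.config.loss == "mse":
            return float(np.mean((pred - y) ** 2))
        return float(np.mean(np.logaddexp(0.0, pred) - y * pred))

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "DenseNet":
        cfg = self.config
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        if n_val < cfg.batch_size:
            raise ValueError(
                f"validation split of {n_val} rows is smaller than one batch "
                f"({cfg.batch_size}); provide more data or a smaller batch size")
        # Start the head at the outcome's base rate: Adam moves parameters by
        # ~lr per step, so asking the bias to travel tens of units wastes the
        # whole epoch budget on learning the mean.
        if cfg.loss == "mse":
            self.params["b_out"][:] = float(np.mean(y))
        else:
            p1 = float(np.clip(np.mean(y), 1e-3, 1 - 1e-3))
            self.params["b_out"][:] = float(np.log(p1 / (1 - p1)))
        rng = self._rng
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        lr = cfg.learning_rate
        best_val = np.inf
        best_params = None
        best_running = None
        wait_es = 0
        wait_lr = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(Xtr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2 and cfg.batch_norm:
                    continue  # batch statistics undefined on one row
                loss, grads = self._backward(Xtr[idx], ytr[idx], rng)
                self._adam_step(grads, lr)
                losses.append(loss)
            val_loss = self._eval_loss(Xval, yval)
            self.history["loss"].append(float(np.mean(losses)))
            self.history["val_loss"].append(val_loss)
            self.history["lr"].append(lr)

            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = copy.deepcopy(self.params)
                best_running = copy.deepcopy(self.running)
                wait_es = 0
                wait_lr = 0
            else:
                wait_es += 1
                wait_lr += 1
            if cfg.lr_schedule == "plateau":
                if wait_lr >= cfg.lr_reduce_patience:
                    lr *= cfg.lr_reduce_factor
                    wait_lr = 0
            elif (epoch + 1) % cfg.lr_reduce_patience == 0:
                lr *= cfg.lr_reduce_factor
            if wait_es >= cfg.early_stop_patience:
                break
        if cfg.restore_best and best_params is not None:
            self.params = best_params
            self.running = best_running
        return self

    # -- inference -------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, float), training=False)
        if self.config.loss == "bce":
            return 1.0 / (1.0 + np.exp(-out))
        return out

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations in inference mode (n x units)."""
        _, cache = self._forward(np.asarray(X, float), training=False)
        return cache["act"][-1]
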