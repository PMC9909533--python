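"""Small convolutional network regressing residue concentration from
the 10 leaf-image statistics.

The feature vector is standardized (training statistics only), embedded
row-major into a 6x6 single-channel grid (cells 0-9; the remaining 26
cells are zero), and pushed through

    conv 2x2 x16 (same pad) + ReLU -> maxpool 2x2/2 ->
    conv 2x2 x32 (same pad) + ReLU -> flatten(288) ->
    dense 512 + ReLU -> dense 1

Weights start from N(0, 0.1), biases at 0.1; training is seeded
mini-batch gradient descent on the mean-squared error at learning rate
0.01 for a fixed iteration budget, with the training loss logged every
`log_every` steps.  The network is implemented directly in NumPy
(im2col convolutions, hand-derived gradients): the model is small
enough that a dense linear-algebra formulation is both fast and exactly
reproducible under a fixed seed.

Labels are standardized internally for optimisation stability and
mapped back to mg/kg at prediction time; logged losses are reported in
mg/kg².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import metrics as _metrics

__all__ = [
    "CNNConfig",
    "TrainLog",
    "TrainingDivergedError",
    "features_to_grid",
    "CNNFeatureRegressor",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class CNNConfig:
    """Architecture and training protocol of the residue network."""

    input_side: int = 6
    conv1_filters: int = 16
    conv2_filters: int = 32
    kernel_size: int = 2
    pool_size: int = 2
    fc_width: int = 512
    weight_init_sd: float = 0.1
    bias_init: float = 0.1
    learning_rate: float = 0.01
    iterations: int = 10_000
    log_every: int = 100
    train_fraction: float = 0.8
    batch_size: int = 128
    optimizer: str = "gd"  # "gd" (plain gradient descent) or "adam"
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_side", "conv1_filters", "conv2_filters",
                     "kernel_size", "pool_size", "fc_width", "iterations",
                     "log_every", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError("optimizer must be 'gd' or 'adam'")


@dataclass
class TrainLog:
    """Loss trace (every `log_every` iterations) and final split metrics."""

    iterations: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    r2: list[float] = field(default_factory=list)
    final: dict = field(default_factory=dict)


def features_to_grid(features: np.ndarray, side: int = 6) -> np.ndarray:
    """Embed standardized feature vectors row-major into side x side
    single-channel grids (n, side, side, 1); unused cells are zero."""
    F = np.atleast_2d(np.asarray(features, dtype=_DTYPE))
    n, p = F.shape
    if p > side * side:
        raise ValueError(f"{p} features do not fit a {side}x{side} grid")
    grids = np.zeros((n, side * side), dtype=_DTYPE)
    grids[:, :p] = F
    return grids.reshape(n, side, side, 1)


# --------------------------------------------------------------------------
# layer primitives (NHWC layout throughout)
# --------------------------------------------------------------------------

def _conv_forward(x, W, b):
    """2D convolution, stride 1, 'same' output via bottom/right padding
    (kernel is even).  W has shape (kh, kw, C_in, C_out)."""
    kh, kw, cin, cout = W.shape
    n, H, Wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (0, kh - 1), (0, kw - 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (n, H, Wd, C, kh, kw) -> cols (n, H, Wd, kh*kw*C)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, H, Wd, kh * kw * cin)
    out = cols @ W.reshape(kh * kw * cin, cout) + b
    return out, cols


def _conv_backward(dout, cols, W, x_shape):
    kh, kw, cin, cout = W.shape
    n, H, Wd, _ = x_shape
    Wr = W.reshape(kh * kw * cin, cout)
    flat = dout.reshape(-1, cout)
    dW = (cols.reshape(-1, kh * kw * cin).T @ flat).reshape(W.shape)
    db = flat.sum(axis=0)
    dcols = (flat @ Wr.T).reshape(n, H, Wd, kh, kw, cin)
    dxp = np.zeros((n, H + kh - 1, Wd + kw - 1, cin), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + H, j:j + Wd, :] += dcols[:, :, :, i, j, :]
    return dxp[:, :H, :Wd, :], dW, db


def _pool_forward(x, k):
    n, H, Wd, C = x.shape
    Ho, Wo = H // k, Wd // k
    r = (x[:, :Ho * k, :Wo * k, :]
         .reshape(n, Ho, k, Wo, k, C)
         .transpose(0, 1, 3, 5, 2, 4)
         .reshape(n, Ho, Wo, C, k * k))
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout, idx, x_shape, k):
    n, H, Wd, C = x_shape
    Ho, Wo = H // k, Wd // k
    dr = np.zeros((n, Ho, Wo, C, k * k), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    return (dr.reshape(n, Ho, Wo, C, k, k)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, Ho * k, Wo * k, C))


def _relu(x):
    return np.maximum(x, 0)


class _Net:
    """Parameter container with forward/backward passes."""

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator):
        s, k = cfg.input_side, cfg.kernel_size
        f1, f2 = cfg.conv1_filters, cfg.conv2_filters
        side2 = s // cfg.pool_size
        self.flat_dim = side2 * side2 * f2
        sd, b0 = cfg.weight_init_sd, cfg.bias_init

        def w(*shape):
            return rng.normal(0.0, sd, size=shape).astype(_DTYPE)

        self.params = {
            "W1": w(k, k, 1, f1), "b1": np.full(f1, b0, dtype=_DTYPE),
            "W2": w(k, k, f1, f2), "b2": np.full(f2, b0, dtype=_DTYPE),
            "W3": w(self.flat_dim, cfg.fc_width),
            "b3": np.full(cfg.fc_width, b0, dtype=_DTYPE),
            "W4": w(cfg.fc_width, 1), "b4": np.full(1, b0, dtype=_DTYPE),
        }
        self.pool = cfg.pool_size

    def forward(self, x, cache: bool = False):
        p = self.params
        z1, cols1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = _relu(z1)
        pool, idx = _pool_forward(a1, self.pool)
        z2, cols2 = _conv_forward(pool, p["W2"], p["b2"])
        a2 = _relu(z2)
        flat = a2.reshape(x.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = _relu(z3)
        out = (a3 @ p["W4"] + p["b4"])[:, 0]
        if not cache:
            return out
        return out, (x, cols1, z1, a1, pool, idx, cols2, z2, a2, flat, z3, a3)

    def backward(self, dout, cache):
        p = self.params
        x, cols1, z1, a1, pool, idx, cols2, z2, a2, flat, z3, a3 = cache
        g = {}
        d = dout[:, None].astype(_DTYPE)
        g["W4"] = a3.T @ d
        g["b4"] = d.sum(axis=0)
        da3 = d @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        dpool, g["W2"], g["b2"] = _conv_backward(dz2, cols2, p["W2"], pool.shape)
        da1 = _pool_backward(dpool, idx, a1.shape, self.pool)
        dz1 = da1 * (z1 > 0)
        _, g["W1"], g["b1"] = _conv_backward(dz1, cols1, p["W1"], x.shape)
        return g

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class CNNFeatureRegressor(RegressorMixin, BaseEstimator):
    """Residue regressor over the 10 image features.

    ``fit(X, y)`` performs the internal 8:2 train/test split, feature
    and label standardization on the training part only, and the seeded
    gradient-descent loop; ``predict`` maps feature rows to mg/kg.

    Attributes
    ----------
    net_ : the fitted network
    train_log_ : :class:`TrainLog` with the loss trace (mg/kg² units)
        and final Press/RMSE/MAE/R² for both internal splits
    train_idx_, test_idx_ : the internal split indices
    """

    def __init__(self, config: CNNConfig | None = None, **overrides):
        self.config = config
        self.overrides = overrides

    def _cfg(self) -> CNNConfig:
        cfg = self.config if self.config is not None else CNNConfig()
        if self.overrides:
            cfg = CNNConfig(**{**asdict(cfg), **self.overrides})
        cfg.validate()
        return cfg

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True, ensure_min_samples=10)
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")
        cfg = self._cfg()
        rng = np.random.default_rng(cfg.seed)

        n = X.shape[0]
        perm = rng.permutation(n)
        n_train = max(2, int(round(cfg.train_fraction * n)))
        n_train = min(n_train, n - 1)
        self.train_idx_ = np.sort(perm[:n_train])
        self.test_idx_ = np.sort(perm[n_train:])

        Xtr, ytr = X[self.train_idx_], y[self.train_idx_].astype(float)
        Xte, yte = X[self.test_idx_], y[self.test_idx_].astype(float)

        self.x_mean_ = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        self.x_std_ = np.where(sd == 0, 1.0, sd)
        self.y_mean_ = float(ytr.mean())
        ysd = float(ytr.std())
        self.y_std_ = ysd if ysd > 0 else 1.0

        gtr = features_to_grid((Xtr - self.x_mean_) / self.x_std_, cfg.input_side)
        ztr = ((ytr - self.y_mean_) / self.y_std_).astype(_DTYPE)

        self.net_ = _Net(cfg, rng)
        self.train_log_ = self._train_loop(self.net_, gtr, ztr, cfg, rng)

        for split, Xs, ys in (("train", Xtr, ytr), ("test", Xte, yte)):
            yhat = self.predict(Xs)
            self.train_log_.final[split] = {
                "press": _metrics.press(ys, yhat),
                "rmse": _metrics.rmse(ys, yhat),
                "mae": _metrics.mae(ys, yhat),
                "r2": _metrics.r2(ys, yhat) if np.ptp(ys) > 0 else float("nan"),
                "n": int(ys.size),
            }
        return self

    def _train_loop(self, net, grids, z, cfg, rng) -> TrainLog:
        n = grids.shape[0]
        bs = min(cfg.batch_size, n)
        lr = _DTYPE(cfg.learning_rate)
        log = TrainLog()
        if cfg.optimizer == "adam":
            m = {k: np.zeros_like(v) for k, v in net.params.items()}
            v = {k: np.zeros_like(va) for k, va in net.params.items()}
            b1, b2, eps = 0.9, 0.999, 1e-8

        order = rng.permutation(n)
        pos = 0
        for it in range(1, cfg.iterations + 1):
            if pos + bs > n:
                order = rng.permutation(n)
                pos = 0
            batch = order[pos:pos + bs]
            pos += bs

            xb, zb = grids[batch], z[batch]
            pred, cache = net.forward(xb, cache=True)
            resid = pred - zb
            grads = net.backward(2.0 * resid / bs, cache)

            if cfg.optimizer == "gd":
                for k in net.params:
                    net.params[k] -= lr * grads[k]
            else:
                for k in net.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1 ** it)
                    vh = v[k] / (1 - b2 ** it)
                    net.params[k] -= lr * mh / (np.sqrt(vh) + eps)

            if it % cfg.log_every == 0 or it == cfg.iterations:
                full = net.forward(grids)
                loss = float(np.mean((full - z) ** 2)) * self.y_std_ ** 2
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"training loss became non-finite at iteration {it}")
                denom = float(np.var(z))
                r2 = 1.0 - float(np.mean((full - z) ** 2)) / denom if denom else 0.0
                log.iterations.append(it)
                log.loss.append(loss)
                log.r2.append(r2)
        return log

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        cfg = self._cfg()
        grids = features_to_grid((X - self.x_mean_) / self.x_std_, cfg.input_side)
        out = np.empty(grids.shape[0])
        # batched forward so predictions are independent of batch makeup
        for start in range(0, grids.shape[0], 4096):
            sl = slice(start, start + 4096)
            out[sl] = self.net_.forward(grids[sl]).astype(float)
        return out * self.y_std_ + self.y_mean_

    # ---- persistence ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self)
        payload = {f"param_{k}": v for k, v in self.net_.params.items()}
        np.savez(
            path, format_version=1,
            config=json.dumps(asdict(self._cfg())),
            x_mean=self.x_mean_, x_std=self.x_std_,
            y_mean=self.y_mean_, y_std=self.y_std_,
            n_features=self.n_features_in_, **payload)

    @classmethod
    def load(cls, path) -> "CNNFeatureRegressor":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"no model file at {path}")
        try:
            with np.load(path, allow_pickle=False) as z:
                cfg = CNNConfig(**json.loads(str(z["config"])))
                est = cls(config=cfg)
                est.net_ = _Net(cfg, np.random.default_rng(0))
                for k in _Net.PARAM_NAMES:
                    est.net_.params[k] = z[f"param_{k}"].astype(_DTYPE)
                est.x_mean_ = z["x_mean"]
                est.x_std_ = z["x_std"]
                est.y_mean_ = float(z["y_mean"])
                est.y_std_ = float(z["y_std"])
                est.n_features_in_ = int(z["n_features"])
        except (KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
            raise ValueError(f"corrupt or incompatible model file {path}: {exc}")
        est.train_log_ = TrainLog()
        return est


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def build_model(cfg: CNNConfig | None = None) -> CNNFeatureRegressor:
    """Unfitted estimator for a config (weights drawn at ``fit`` time)."""
    return CNNFeatureRegressor(config=cfg or CNNConfig())


def train(features, y, cfg: CNNConfig | None = None) -> CNNFeatureRegressor:
    return build_model(cfg).fit(features, y)


def predict(model: CNNFeatureRegressor, features) -> np.ndarray:
    return model.predict(features)


def save_model(model: CNNFeatureRegressor, path) -> None:
    model.save(path)


def load_model(path) -> CNNFeatureRegressor:
    return CNNFeatureRegressor.load(path)
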