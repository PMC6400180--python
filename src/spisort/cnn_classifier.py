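"""A deliberately tiny supervised CNN for diffraction-pattern sorting.

Three convolutional layers (3x3 kernels, no conv bias), each followed by
batch normalization, ReLU, 2x2 max-pooling and dropout; then one hidden
dense unit and a single sigmoid output.  With 64x64 inputs the default
architecture has exactly 316 trainable parameters — fewer parameters than
the 200-image training sets it is meant for, which is the whole point: a
network this small cannot memorize a small hand-labelled set.

Implemented directly on numpy (im2col convolutions, hand-written backprop,
Adam); at this size a deep-learning framework would be heavier than the
network itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import LabelSet
from .preprocess import FeatureImage

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "TinyCNN",
    "build_cnn",
    "count_parameters",
    "spec_parameter_count",
    "train_cnn",
    "predict_cnn",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class CNNSpec:
    """Architecture hyper-parameters; the defaults realize the 316-parameter
    configuration for 64x64 inputs."""

    input_size: Tuple[int, int] = (64, 64)
    conv_channels: Tuple[int, int, int] = (2, 2, 3)
    kernel_size: int = 3
    conv_bias: bool = False
    hidden_units: int = 1
    dropout_rate: float = 0.2
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three convolutional layers required")
        h, w = self.input_size
        if h % 8 or w % 8:
            raise ValueError("input size must survive three 2x2 poolings")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def flat_features(self) -> int:
        h, w = self.input_size
        return (h // 8) * (w // 8) * self.conv_channels[-1]


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    loss: str = "bce"
    rng_seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer != "adam" or self.loss != "bce":
            raise ValueError("only adam + binary cross-entropy are provided")


def spec_parameter_count(spec: CNNSpec) -> int:
    """Closed-form trainable-parameter count of a spec (no model needed)."""
    total = 0
    c_in = 1
    for c_out in spec.conv_channels:
        total += spec.kernel_size ** 2 * c_in * c_out
        if spec.conv_bias:
            total += c_out
        if spec.batch_norm:
            total += 2 * c_out
        c_in = c_out
    total += spec.hidden_units * spec.flat_features + spec.hidden_units
    total += spec.hidden_units  # output unit, no bias
    return total


class TinyCNN:
    """The network: parameters, forward pass and hand-written backward pass."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel_size
        self.params: Dict[str, np.ndarray] = {}
        c_in = 1
        for n, c_out in enumerate(spec.conv_channels, start=1):
            fan_in = c_in * k * k
            self.params[f"W{n}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
            if spec.conv_bias:
                self.params[f"cb{n}"] = np.zeros(c_out)
            if spec.batch_norm:
                self.params[f"g{n}"] = np.ones(c_out)
                self.params[f"b{n}"] = np.zeros(c_out)
            c_in = c_out
        f = spec.flat_features
        self.params["Wh"] = rng.normal(0.0, np.sqrt(2.0 / f),
                                       (spec.hidden_units, f))
        self.params["bh"] = np.full(spec.hidden_units, 0.01)
        self.params["Wo"] = np.ones((1, spec.hidden_units))
        self.running: Dict[str, np.ndarray] = {}
        if spec.batch_norm:
            for n, c_out in enumerate(spec.conv_channels, start=1):
                self.running[f"mean{n}"] = np.zeros(c_out)
                self.running[f"var{n}"] = np.ones(c_out)

    # -- primitive layers ---------------------------------------------------

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        k = w.shape[-1]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.einsum("bchwij,ocij->bohw", win, w), win

    @staticmethod
    def _conv_backward(dout, win, w, x_shape):
        k = w.shape[-1]
        p = k // 2
        dw = np.einsum("bchwij,bohw->ocij", win, dout)
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        dwin = sliding_window_view(dp, (k, k), axis=(2, 3))
        dx = np.einsum("bohwij,ocij->bchw", dwin, w[:, :, ::-1, ::-1])
        return dx, dw

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Returns per-sample logits and (in training mode) a backprop cache."""
        spec = self.spec
        cache: Dict = {"training": training}
        h = x[:, None, :, :] if x.ndim == 3 else x
        for n in range(1, 4):
            w = self.params[f"W{n}"]
            h, win = self._conv(h, w)
            cache[f"win{n}"] = win
            if spec.conv_bias:
                h = h + self.params[f"cb{n}"][None, :, None, None]
            if spec.batch_norm:
                h, bn_cache = self._bn_forward(h, n, training)
                cache[f"bn{n}"] = bn_cache
            cache[f"pre_relu{n}"] = h
            h = np.maximum(h, 0.0)
            h, pool_idx = self._pool_forward(h)
            cache[f"pool{n}"] = pool_idx
            if training and spec.dropout_rate > 0:
                keep = rng.random(h.shape) >= spec.dropout_rate
                h = h * keep / (1.0 - spec.dropout_rate)
                cache[f"drop{n}"] = keep
            cache[f"out{n}"] = h
        flat = h.reshape(len(h), -1)
        cache["flat"] = flat
        # identity activation on the 1-unit hidden layer: a rectified
        # bottleneck this narrow can die irreversibly during training
        hid = flat @ self.params["Wh"].T + self.params["bh"]
        cache["hid"] = hid
        logits = (hid @ self.params["Wo"].T)[:, 0]
        return logits, cache

    def _bn_forward(self, x, n, training):
        g = self.params[f"g{n}"][None, :, None, None]
        b = self.params[f"b{n}"][None, :, None, None]
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running[f"mean{n}"] = ((1 - _BN_MOMENTUM) * self.running[f"mean{n}"]
                                        + _BN_MOMENTUM * mu)
            self.running[f"var{n}"] = ((1 - _BN_MOMENTUM) * self.running[f"var{n}"]
                                       + _BN_MOMENTUM * var)
        else:
            mu = self.running[f"mean{n}"]
            var = self.running[f"var{n}"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        return g * xhat + b, (xhat, inv, x - mu[None, :, None, None])

    @staticmethod
    def _pool_forward(x):
        b, c, hh, ww = x.shape
        xr = x.reshape(b, c, hh // 2, 2, ww // 2, 2)
        out = xr.max(axis=(3, 5))
        ties = xr == out[:, :, :, None, :, None]
        counts = ties.sum(axis=(3, 5))
        return out, (ties, counts)

    # -- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: Dict) -> Dict[str, np.ndarray]:
        spec = self.spec
        grads: Dict[str, np.ndarray] = {}
        hid = cache["hid"]
        grads["Wo"] = dlogits[None, :] @ hid
        dhid = dlogits[:, None] @ self.params["Wo"]
        grads["Wh"] = dhid.T @ cache["flat"]
        grads["bh"] = dhid.sum(axis=0)
        dflat = dhid @ self.params["Wh"]
        h = cache["out3"]
        dh = dflat.reshape(h.shape)
        for n in range(3, 0, -1):
            if cache["training"] and spec.dropout_rate > 0:
                dh = dh * cache[f"drop{n}"] / (1.0 - spec.dropout_rate)
            dh = self._pool_backward(dh, cache[f"pool{n}"])
            dh = dh * (cache[f"pre_relu{n}"] > 0)
            if spec.batch_norm:
                dh, dg, db = self._bn_backward(dh, n, cache[f"bn{n}"],
                                               cache["training"])
                grads[f"g{n}"] = dg
                grads[f"b{n}"] = db
            if spec.conv_bias:
                grads[f"cb{n}"] = dh.sum(axis=(0, 2, 3))
            dh, dw = self._conv_backward(dh, cache[f"win{n}"],
                                         self.params[f"W{n}"], None)
            grads[f"W{n}"] = dw
        return grads

    def _bn_backward(self, dout, n, bn_cache, training):
        xhat, inv, xc = bn_cache
        g = self.params[f"g{n}"]
        dg = (dout * xhat).sum(axis=(0, 2, 3))
        db = dout.sum(axis=(0, 2, 3))
        dxhat = dout * g[None, :, None, None]
        if not training:
            return dxhat * inv[None, :, None, None], dg, db
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        invb = inv[None, :, None, None]
        dvar = (dxhat * xc * -0.5 * invb ** 3).sum(axis=(0, 2, 3))
        dmu = ((-dxhat * invb).sum(axis=(0, 2, 3))
               + dvar * (-2.0 / m) * xc.sum(axis=(0, 2, 3)))
        dx = (dxhat * invb
              + dvar[None, :, None, None] * 2.0 * xc / m
              + dmu[None, :, None, None] / m)
        return dx, dg, db

    @staticmethod
    def _pool_backward(dout, pool_cache):
        ties, counts = pool_cache
        b, c, h2, _, w2, _ = ties.shape
        spread = (dout / counts)[:, :, :, None, :, None] * ties
        return spread.reshape(b, c, h2 * 2, w2 * 2)

    # -- inference ----------------------------------------------------------

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid scores in [0, 1]; dropout off, batch norm on running stats."""
        logits, _ = self.forward(np.asarray(x, dtype=float), training=False)
        return 1.0 / (1.0 + np.exp(-logits))


def build_cnn(spec: Optional[CNNSpec] = None, seed: int = 0) -> TinyCNN:
    """Instantiate the network; with the default spec, 316 parameters."""
    return TinyCNN(spec if spec is not None else CNNSpec(), seed=seed)


def count_parameters(model: Optional[TinyCNN]) -> int:
    """Sum of trainable array sizes (pool/dropout layers hold none)."""
    if model is None:
        return 0
    return int(sum(p.size for p in model.params.values()))


def _as_images(images) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(images, np.ndarray):
        return images.astype(float), np.arange(len(images)).astype(object)
    arr = np.stack([f.values for f in images]).astype(float)
    ids = np.array([f.pattern_id for f in images], dtype=object)
    return arr, ids


def train_cnn(model: TinyCNN, images, labels, config: Optional[TrainConfig] = None
              ) -> Tuple[TinyCNN, Dict[str, List[float]]]:
    """Minimize binary cross-entropy with Adam; reproducible from the seed.

    Returns the trained model (updated in place) and a history with
    per-epoch mean training loss and accuracy.
    """
    config = config if config is not None else TrainConfig()
    x, _ = _as_images(images)
    y = np.asarray(labels, dtype=float)
    if len(x) != len(y):
        raise ValueError("one label per image required")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError("need at least two examples per class")
    if x.shape[1:] != model.spec.input_size:
        raise ValueError(f"images must be {model.spec.input_size}")

    rng = np.random.default_rng(config.rng_seed)
    mom1 = {k: np.zeros_like(v) for k, v in model.params.items()}
    mom2 = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    n = len(x)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            prob = 1.0 / (1.0 + np.exp(-logits))
            loss = -np.mean(yb * np.log(prob + 1e-12)
                            + (1 - yb) * np.log(1 - prob + 1e-12))
            losses.append(loss * len(idx))
            hits += int(((prob > 0.5) == (yb > 0.5)).sum())
            dlogits = (prob - yb) / len(idx)
            grads = model.backward(dlogits, cache)
            step += 1
            for key, g in grads.items():
                mom1[key] = b1 * mom1[key] + (1 - b1) * g
                mom2[key] = b2 * mom2[key] + (1 - b2) * g * g
                m_hat = mom1[key] / (1 - b1 ** step)
                v_hat = mom2[key] / (1 - b2 ** step)
                model.params[key] -= (config.learning_rate * m_hat
                                      / (np.sqrt(v_hat) + eps))
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(hits / n)
    return model, history


def fit_cnn(images, labels, spec: Optional[CNNSpec] = None,
            config: Optional[TrainConfig] = None, n_restarts: int = 3,
            seed: int = 0) -> Tuple[TinyCNN, Dict[str, List[float]]]:
    """Train with several random restarts and keep the best fit.

    A 316-parameter network trained by Adam occasionally settles in a poor
    optimum for an unlucky initialization; restarting from a few seeds and
    selecting by final *training* loss (never held-out data) makes the fit
    robust while staying fully deterministic given ``seed``.
    """
    base = config if config is not None else TrainConfig()
    best_model, best_hist, best_loss = None, None, np.inf
    for r in range(max(n_restarts, 1)):
        sub = (seed + 7919 * r) % (2 ** 31)
        model = TinyCNN(spec if spec is not None else CNNSpec(), seed=sub)
        cfg = TrainConfig(epochs=base.epochs, batch_size=base.batch_size,
                          learning_rate=base.learning_rate,
                          optimizer=base.optimizer, loss=base.loss,
                          rng_seed=sub,
                          validation_fraction=base.validation_fraction)
        model, hist = train_cnn(model, images, labels, cfg)
        final = hist["loss"][-1] if hist["loss"] else np.inf
        if final < best_loss:
            best_model, best_hist, best_loss = model, hist, final
    return best_model, best_hist


def predict_cnn(model: TinyCNN, images, theta: float = 0.5) -> LabelSet:
    """Score patterns and threshold at ``theta`` (class 1 = single hit)."""
    x, ids = _as_images(images)
    if x.shape[1:] != model.spec.input_size:
        raise ValueError(f"images must be {model.spec.input_size}")
    return LabelSet(ids=ids, scores=model.scores(x), threshold=theta)


def save_checkpoint(model: TinyCNN, path: str) -> None:
    """Single-archive checkpoint: architecture spec + weights + BN stats."""
    meta = json.dumps(asdict(model.spec))
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"running_{k}": v for k, v in model.running.items()})
    np.savez(path, spec=np.bytes_(meta.encode()), **arrays)


def load_checkpoint(path: str) -> TinyCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["spec"].item()).decode())
        meta["input_size"] = tuple(meta["input_size"])
        meta["conv_channels"] = tuple(meta["conv_channels"])
        model = TinyCNN(CNNSpec(**meta))
        for key in data.files:
            if key.startswith("param_"):
                model.params[key[6:]] = data[key]
            elif key.startswith("running_"):
                model.running[key[8:]] = data[key]
    return model
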