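"""Stacked autoencoder feature compression.

A funnel of tied-weight sigmoid autoencoders (layer sizes 256, 128, 64 by
default) trained greedily layer by layer: layer l minimizes the mean squared
reconstruction error of the previous layer's codes, then is frozen and its
codes feed layer l+1.  The 64-unit bottleneck code is the compressed
representation used downstream.  Inputs are min-max scaled to [0, 1] per
feature (a sigmoid decoder cannot reconstruct unbounded values); the scaler
is part of the fitted model.

Training uses Glorot-uniform initialization, Adam (lr 1e-3), minibatches of
128, up to 20 epochs per layer with early stopping (patience 3) on a 10%
held-out slice, restoring the best weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("circmi")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class _Adam:
    """Adam with optional per-parameter learning-rate scales."""

    def __init__(self, shapes, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8, lr_scales=None):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.scales = lr_scales if lr_scales is not None else [1.0] * len(self.m)
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * self.scales[i] * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class SaeLayer:
    """One tied autoencoder layer: encode y = s(x W^T + b), decode s(y W + b')."""

    weights: np.ndarray  # (h_l, h_{l-1})
    bias_enc: np.ndarray  # (h_l,)
    bias_dec: np.ndarray  # (h_{l-1},)
    decoder_weights: np.ndarray | None = None  # untied variant only

    def encode(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(x @ self.weights.T + self.bias_enc)

    def decode(self, y: np.ndarray) -> np.ndarray:
        W_dec = self.weights if self.decoder_weights is None else self.decoder_weights
        return _sigmoid(y @ W_dec + self.bias_dec)


@dataclass
class SaeModel:
    layers: list[SaeLayer]
    sizes: tuple[int, ...]
    feature_min: np.ndarray
    feature_range: np.ndarray
    history: list[dict] = field(default_factory=list)  # per layer: train/val loss traces
    seed: int = 0

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_min) / self.feature_range


def _layer_mse(layer: SaeLayer, X: np.ndarray) -> float:
    return float(np.mean((layer.decode(layer.encode(X)) - X) ** 2))


def _train_layer(
    X: np.ndarray,
    n_hidden: int,
    rng: np.random.Generator,
    epochs: int,
    lr: float,
    batch_size: int,
    val_frac: float,
    patience: int,
    tied: bool,
) -> tuple[SaeLayer, dict]:
    n, d = X.shape
    n_val = max(1, int(round(val_frac * n)))
    if n_val >= n:
        raise ValueError(f"{n} samples cannot spare a {val_frac:.0%} validation slice")
    order = rng.permutation(n)
    train, val = X[order[n_val:]], X[order[:n_val]]

    layer = SaeLayer(
        weights=_glorot(rng, n_hidden, d),
        bias_enc=np.zeros(n_hidden),
        bias_dec=np.zeros(d),
        decoder_weights=None if tied else _glorot(rng, n_hidden, d),
    )
    params = [layer.weights, layer.bias_enc, layer.bias_dec]
    if not tied:
        params.append(layer.decoder_weights)
    opt = _Adam([p.shape for p in params], lr=lr)

    best = {"val": np.inf, "params": [p.copy() for p in params], "epoch": -1}
    trace = {"train": [], "val": []}
    bad_epochs = 0
    n_train = len(train)
    for epoch in range(epochs):
        perm = rng.permutation(n_train)
        for lo in range(0, n_train, batch_size):
            xb = train[perm[lo : lo + batch_size]]
            y = layer.encode(xb)
            xhat = layer.decode(y)
            g2 = (xhat - xb) * xhat * (1 - xhat) * (2.0 / xb.shape[0])
            W_dec = layer.weights if tied else layer.decoder_weights
            g1 = (g2 @ W_dec.T) * y * (1 - y)
            gW = g1.T @ xb
            if tied:
                gW = gW + (y.T @ g2)
                grads = [gW, g1.sum(axis=0), g2.sum(axis=0)]
            else:
                grads = [gW, g1.sum(axis=0), g2.sum(axis=0), y.T @ g2]
            opt.step(params, grads)
        trace["train"].append(_layer_mse(layer, train))
        val_loss = _layer_mse(layer, val)
        trace["val"].append(val_loss)
        if val_loss < best["val"] - 1e-12:
            best = {"val": val_loss, "params": [p.copy() for p in params], "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > patience:
                break
    for p, bp in zip(params, best["params"]):
        p[...] = bp
    trace["best_epoch"] = best["epoch"]
    trace["best_val"] = best["val"]
    return layer, trace


def sae_fit(
    X: np.ndarray,
    sizes: tuple[int, ...] = (256, 128, 64),
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 128,
    val_frac: float = 0.10,
    patience: int = 3,
    seed: int = 0,
    tied: bool = True,
) -> SaeModel:
    """Greedy layer-wise training of the stacked autoencoder."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    fmin = X.min(axis=0)
    frange = X.max(axis=0) - fmin
    frange = np.where(frange > 0, frange, 1.0)
    Xs = (X - fmin) / frange

    rng = np.random.default_rng(seed)
    layers: list[SaeLayer] = []
    history: list[dict] = []
    codes = Xs
    for n_hidden in sizes:
        layer, trace = _train_layer(
            codes, n_hidden, rng, epochs, lr, batch_size, val_frac, patience, tied
        )
        layers.append(layer)
        history.append(trace)
        codes = layer.encode(codes)
        logger.info(
            "SAE layer %d->%d: best val MSE %.3g (epoch %d)",
            layer.weights.shape[1],
            n_hidden,
            trace["best_val"],
            trace["best_epoch"],
        )
    return SaeModel(
        layers=layers,
        sizes=tuple(sizes),
        feature_min=fmin,
        feature_range=frange,
        history=history,
        seed=seed,
    )


def sae_encode(model: SaeModel, X: np.ndarray, depth: int | str = "bottleneck") -> np.ndarray:
    """Forward pass up to ``depth`` (1-based layer index, or "bottleneck")."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.layers[0].weights.shape[1]:
        raise ValueError(
            f"expected {model.layers[0].weights.shape[1]} features, got {X.shape[1]}"
        )
    n_layers = len(model.layers) if depth == "bottleneck" else int(depth)
    if not 1 <= n_layers <= len(model.layers):
        raise ValueError(f"depth must be in 1..{len(model.layers)}")
    codes = model.scale(X)
    for layer in model.layers[:n_layers]:
        codes = layer.encode(codes)
    return codes


def sae_save(model: SaeModel, path) -> None:
    """Serialize scaler and per-layer parameters to one .npz container."""
    arrays = {
        "sizes": np.asarray(model.sizes),
        "seed": np.asarray(model.seed),
        "feature_min": model.feature_min,
        "feature_range": model.feature_range,
    }
    for i, layer in enumerate(model.layers):
        arrays[f"W{i}"] = layer.weights
        arrays[f"be{i}"] = layer.bias_enc
        arrays[f"bd{i}"] = layer.bias_dec
        if layer.decoder_weights is not None:
            arrays[f"Wd{i}"] = layer.decoder_weights
    np.savez(path, **arrays)


def sae_load(path) -> SaeModel:
    data = np.load(path)
    sizes = tuple(int(s) for s in data["sizes"])
    layers = [
        SaeLayer(
            weights=data[f"W{i}"],
            bias_enc=data[f"be{i}"],
            bias_dec=data[f"bd{i}"],
            decoder_weights=data[f"Wd{i}"] if f"Wd{i}" in data else None,
        )
        for i in range(len(sizes))
    ]
    return SaeModel(
        layers=layers,
        sizes=sizes,
        feature_min=data["feature_min"],
        feature_range=data["feature_range"],
        seed=int(data["seed"]),
    )


def sae_reconstruct(model: SaeModel, X: np.ndarray) -> np.ndarray:
    """Encode to the bottleneck and decode back; returns the scaled-space
    reconstruction (compare against ``model.scale(X)``)."""
    codes = sae_encode(model, X, "bottleneck")
    for layer in reversed(model.layers):
        codes = layer.decode(codes)
    return codes
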