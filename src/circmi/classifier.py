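"""MLP link classifier trained jointly with the attention fusion stages.

Architecture: fused pair vector (dim 2(64+H)) -> one hidden layer of 100
ReLU units -> sigmoid output.  The loss is binary cross-entropy plus an L2
penalty (coefficient 1e-4) on the weight matrices, minimized with Adam
(lr 1e-3) for up to 5000 optimizer steps.  Gradients flow through the
fusion graph into the four attention heads; the sequence codes and
structural vectors themselves are frozen inputs, standardized with
statistics fitted on the training pairs.

The iteration budget is read as optimizer steps; training is minibatch
(batch 128) by default, with optional early stopping (patience in steps) on
a held-out validation slice of the training pairs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from circmi.attention_fusion import (
    FusionParams,
    fuse_backward,
    fuse_pairs,
    init_fusion,
    standardize,
)
from circmi.deep_features import _Adam, _sigmoid

logger = logging.getLogger("circmi")

Blocks = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]


@dataclass
class ClassifierConfig:
    hidden: int = 100
    l2: float = 1e-4
    lr: float = 1e-3
    max_iter: int = 5000
    batch_size: int | None = 128  # None = full batch
    early_stopping: bool = False
    val_frac: float = 0.125
    patience: int = 200
    # attention heads train on a slower time scale than the MLP: at parity
    # speed the learned re-scaling churns the representation faster than
    # the classifier can track it
    attn_lr_scale: float = 0.01
    fusion_mode: str = "attention"
    fusion_ratios: tuple[float, float] = (1.0, 1.0)
    seed: int = 0


@dataclass
class MlpModel:
    w1: np.ndarray  # (d, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 1)
    b2: np.ndarray

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.maximum(X @ self.w1 + self.b1, 0.0)
        return _sigmoid(h @ self.w2 + self.b2).ravel()


@dataclass
class CmiClassifier:
    """Trained fusion + MLP model with its standardization statistics.

    ``stats`` standardizes the raw input blocks; ``fused_stats``
    standardizes the fused vector before the MLP (fitted once on the
    training pairs at fusion initialization and then held fixed, so the
    transform stays affine while attention parameters train).
    """

    fusion: FusionParams
    mlp: MlpModel
    stats: tuple[np.ndarray, np.ndarray]
    fused_stats: tuple[np.ndarray, np.ndarray]
    config: ClassifierConfig


@dataclass
class TrainingRun:
    loss_trace: list[float] = field(default_factory=list)
    final_loss: float = float("nan")
    seconds: float = 0.0
    seed: int = 0
    stopped_at: int = 0


def _split_blocks(Xz: np.ndarray, d_seq: int, d_str: int) -> Blocks:
    i1, i2, i3 = d_seq, 2 * d_seq, 2 * d_seq + d_str
    return Xz[:, :i1], Xz[:, i1:i2], Xz[:, i2:i3], Xz[:, i3:]


def _forward(fusion, mlp, Xz, d_seq, d_str, fused_stats, need_cache=False):
    blocks = _split_blocks(Xz, d_seq, d_str)
    if need_cache:
        fused_raw, cache = fuse_pairs(fusion, *blocks, return_cache=True)
    else:
        fused_raw = fuse_pairs(fusion, *blocks)
        cache = None
    fused, _ = standardize(fused_raw, stats=fused_stats)
    h = np.maximum(fused @ mlp.w1 + mlp.b1, 0.0)
    p = _sigmoid(h @ mlp.w2 + mlp.b2).ravel()
    return p, fused, h, cache


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def model_fit(
    features: np.ndarray,
    labels: np.ndarray,
    seq_dim: int = 64,
    struct_dim: int = 64,
    config: ClassifierConfig | None = None,
) -> tuple[CmiClassifier, TrainingRun]:
    """Fit the joint fusion + MLP model.

    ``features`` is the raw per-pair block matrix
    [circ_code | mi_code | circ_struct | mi_struct] of width
    2*seq_dim + 2*struct_dim; standardization is fitted here on the
    training pairs.
    """
    config = config or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features/labels length mismatch")
    if X.shape[1] != 2 * seq_dim + 2 * struct_dim:
        raise ValueError(
            f"expected width {2 * seq_dim + 2 * struct_dim}, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or class_counts.min() < 2:
        raise ValueError("need >= 2 samples of each class")

    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    Xz, stats = standardize(X)

    fusion = init_fusion(
        seq_dim,
        struct_dim,
        seed=config.seed,
        mode=config.fusion_mode,
        ratios=config.fusion_ratios,
    )
    d_fused = 2 * (seq_dim + struct_dim)
    lim1 = np.sqrt(6.0 / (d_fused + config.hidden))
    lim2 = np.sqrt(6.0 / (config.hidden + 1))
    mlp = MlpModel(
        w1=rng.uniform(-lim1, lim1, size=(d_fused, config.hidden)),
        b1=np.zeros(config.hidden),
        w2=rng.uniform(-lim2, lim2, size=(config.hidden, 1)),
        b2=np.zeros(1),
    )

    blocks_all = _split_blocks(Xz, seq_dim, struct_dim)
    fused_init = fuse_pairs(fusion, *blocks_all)
    _, fused_stats = standardize(fused_init)

    attn = config.fusion_mode == "attention"
    params: list[np.ndarray] = [mlp.w1, mlp.b1, mlp.w2, mlp.b2]
    if attn:
        params += [
            fusion.stage1_circ.weight, fusion.stage1_circ.bias,
            fusion.stage1_mi.weight, fusion.stage1_mi.bias,
            fusion.stage2_circ.weight, fusion.stage2_circ.bias,
            fusion.stage2_mi.weight, fusion.stage2_mi.bias,
        ]
    lr_scales = [1.0] * 4 + [config.attn_lr_scale] * (len(params) - 4)
    opt = _Adam([p.shape for p in params], lr=config.lr, lr_scales=lr_scales)

    n = len(y)
    if config.early_stopping:
        n_val = max(2, int(round(config.val_frac * n)))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
    else:
        train_idx = rng.permutation(n)
        val_idx = np.empty(0, dtype=int)
    Xtr, ytr = Xz[train_idx], y[train_idx]
    Xval, yval = Xz[val_idx], y[val_idx]
    n_train = len(ytr)
    bsz = config.batch_size or n_train

    run = TrainingRun(seed=config.seed)
    best_val = np.inf
    best_params = None
    bad_steps = 0
    cursor = n_train  # force an initial shuffle
    perm = np.empty(0, dtype=int)
    for it in range(config.max_iter):
        if cursor + bsz > n_train:
            perm = rng.permutation(n_train)
            cursor = 0
        sel = perm[cursor : cursor + bsz]
        cursor += bsz
        xb, yb = Xtr[sel], ytr[sel]

        p, fused, h, cache = _forward(
            fusion, mlp, xb, seq_dim, struct_dim, fused_stats, need_cache=attn
        )
        m = len(yb)
        loss = _bce(yb, p) + config.l2 * (
            np.sum(mlp.w1**2) + np.sum(mlp.w2**2)
        )
        run.loss_trace.append(loss)

        d_logit = ((p - yb) / m)[:, None]  # BCE + sigmoid combined gradient
        g_w2 = h.T @ d_logit + 2 * config.l2 * mlp.w2
        g_b2 = d_logit.sum(axis=0)
        d_h = (d_logit @ mlp.w2.T) * (h > 0)
        g_w1 = fused.T @ d_h + 2 * config.l2 * mlp.w1
        g_b1 = d_h.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        if attn:
            g_fused = (d_h @ mlp.w1.T) / fused_stats[1]
            fg = fuse_backward(fusion, cache, g_fused)
            grads += [
                fg["s1c_W"], fg["s1c_b"], fg["s1m_W"], fg["s1m_b"],
                fg["s2c_W"], fg["s2c_b"], fg["s2m_W"], fg["s2m_b"],
            ]
        opt.step(params, grads)

        if config.early_stopping:
            p_val, _, _, _ = _forward(fusion, mlp, Xval, seq_dim, struct_dim, fused_stats)
            val_loss = _bce(yval, p_val)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = [p.copy() for p in params]
                bad_steps = 0
            else:
                bad_steps += 1
                if bad_steps > config.patience:
                    break
        run.stopped_at = it + 1

    if config.early_stopping and best_params is not None:
        for p, bp in zip(params, best_params):
            p[...] = bp

    p_all, _, _, _ = _forward(fusion, mlp, Xz, seq_dim, struct_dim, fused_stats)
    run.final_loss = _bce(y, p_all)
    run.seconds = time.perf_counter() - t0
    logger.info(
        "classifier trained: %d step(s), final BCE %.4f (%.1fs)",
        run.stopped_at,
        run.final_loss,
        run.seconds,
    )
    model = CmiClassifier(
        fusion=fusion, mlp=mlp, stats=stats, fused_stats=fused_stats, config=config
    )
    return model, run


def predict_scores(model: CmiClassifier, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; scores in the open interval (0, 1)."""
    X = np.asarray(features, dtype=float)
    Xz, _ = standardize(X, stats=model.stats)
    d_seq = model.fusion.seq_dim
    d_str = model.fusion.struct_dim
    p, _, _, _ = _forward(model.fusion, model.mlp, Xz, d_seq, d_str, model.fused_stats)
    return p


def predict_labels(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff score >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def save_model(model: CmiClassifier, path) -> None:
    """Serialize all parameters and config to one .npz container."""
    import json

    cfg = model.config
    arrays = {
        "w1": model.mlp.w1, "b1": model.mlp.b1,
        "w2": model.mlp.w2, "b2": model.mlp.b2,
        "s1c_W": model.fusion.stage1_circ.weight, "s1c_b": model.fusion.stage1_circ.bias,
        "s1m_W": model.fusion.stage1_mi.weight, "s1m_b": model.fusion.stage1_mi.bias,
        "s2c_W": model.fusion.stage2_circ.weight, "s2c_b": model.fusion.stage2_circ.bias,
        "s2m_W": model.fusion.stage2_mi.weight, "s2m_b": model.fusion.stage2_mi.bias,
        "stats_mean": model.stats[0], "stats_sd": model.stats[1],
        "fused_mean": model.fused_stats[0], "fused_sd": model.fused_stats[1],
        "config_json": np.frombuffer(
            json.dumps(
                {
                    "hidden": cfg.hidden, "l2": cfg.l2, "lr": cfg.lr,
                    "max_iter": cfg.max_iter, "batch_size": cfg.batch_size,
                    "early_stopping": cfg.early_stopping, "val_frac": cfg.val_frac,
                    "patience": cfg.patience, "attn_lr_scale": cfg.attn_lr_scale,
                    "fusion_mode": cfg.fusion_mode,
                    "fusion_ratios": list(cfg.fusion_ratios), "seed": cfg.seed,
                }
            ).encode(),
            dtype=np.uint8,
        ),
    }
    np.savez(path, **arrays)


def load_model(path) -> CmiClassifier:
    import json

    from circmi.attention_fusion import AttentionStage

    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["fusion_ratios"] = tuple(cfg_dict["fusion_ratios"])
    config = ClassifierConfig(**cfg_dict)
    fusion = FusionParams(
        stage1_circ=AttentionStage(data["s1c_W"], data["s1c_b"]),
        stage1_mi=AttentionStage(data["s1m_W"], data["s1m_b"]),
        stage2_circ=AttentionStage(data["s2c_W"], data["s2c_b"]),
        stage2_mi=AttentionStage(data["s2m_W"], data["s2m_b"]),
        mode=config.fusion_mode,
        ratios=config.fusion_ratios,
    )
    mlp = MlpModel(w1=data["w1"], b1=data["b1"], w2=data["w2"], b2=data["b2"])
    return CmiClassifier(
        fusion=fusion,
        mlp=mlp,
        stats=(data["stats_mean"], data["stats_sd"]),
        fused_stats=(data["fused_mean"], data["fused_sd"]),
        config=config,
    )
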