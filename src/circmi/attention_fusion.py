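"""Two-stage weighted attention fusion of sequence and structure features.

Per pair, the inputs are the circRNA sequence code (64-d SAE bottleneck),
the miRNA sequence code (64-d), and the GraRep node vectors of both
molecules (H-d each).  Stage 1 attends over the feature positions of each
sequence code: a = softmax(x W + b), attended x = x * a.  Each attended
sequence code is then concatenated with its molecule's structural vector
and stage 2 attends over the concatenation.  The fused output

    N_output = [C_circ_att, C_mi_att]

has dimension 2 * (64 + H).  Attention here is over feature dimensions, not
sequence positions; every weight row is positive and sums to one.

Attention parameters are trained jointly with the downstream classifier
(see :mod:`circmi.classifier`); this module provides the forward pass, the
analytic backward pass, a static-ratio baseline mode, and feature
standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("circmi")


@dataclass
class AttentionStage:
    """One attention head: logits = X W + b, weights = softmax per row."""

    weight: np.ndarray  # (d, d)
    bias: np.ndarray  # (d,)


def init_stage(dim: int, rng: np.random.Generator) -> AttentionStage:
    """Zero-initialized head: the softmax starts exactly uniform (1/d per
    position), so training refines the weighting from an identity-like
    re-scaling instead of a random one."""
    del rng  # deterministic init; signature kept for symmetry with other inits
    return AttentionStage(weight=np.zeros((dim, dim)), bias=np.zeros(dim))


@dataclass
class FusionParams:
    """Four attention heads (circ/mi x stage 1/2) plus the fusion mode."""

    stage1_circ: AttentionStage
    stage1_mi: AttentionStage
    stage2_circ: AttentionStage
    stage2_mi: AttentionStage
    mode: str = "attention"  # "attention" | "static"
    ratios: tuple[float, float] = (1.0, 1.0)  # (sequence, structure), static mode

    @property
    def seq_dim(self) -> int:
        return self.stage1_circ.weight.shape[0]

    @property
    def struct_dim(self) -> int:
        return self.stage2_circ.weight.shape[0] - self.seq_dim


def init_fusion(
    seq_dim: int,
    struct_dim: int,
    seed: int = 0,
    mode: str = "attention",
    ratios: tuple[float, float] = (1.0, 1.0),
) -> FusionParams:
    rng = np.random.default_rng(seed)
    return FusionParams(
        stage1_circ=init_stage(seq_dim, rng),
        stage1_mi=init_stage(seq_dim, rng),
        stage2_circ=init_stage(seq_dim + struct_dim, rng),
        stage2_mi=init_stage(seq_dim + struct_dim, rng),
        mode=mode,
        ratios=ratios,
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def attention_weights(X: np.ndarray, stage: AttentionStage) -> np.ndarray:
    """Per-sample softmax weights over feature positions; rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite attention input")
    return _softmax(X @ stage.weight + stage.bias)


def apply_attention(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Hadamard product of features and their attention weights."""
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if X.shape != weights.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {weights.shape}")
    return X * weights


def _static_weights(params: FusionParams, n: int) -> dict[str, np.ndarray]:
    """Fixed block-ratio weights mimicking a softmax row (sum 1 per row)."""
    d_seq, d_str = params.seq_dim, params.struct_dim
    r_seq, r_str = params.ratios
    w1 = np.full(d_seq, 1.0 / d_seq)
    total = d_seq * r_seq + d_str * r_str
    w2 = np.concatenate([np.full(d_seq, r_seq / total), np.full(d_str, r_str / total)])
    return {
        "a1c": np.tile(w1, (n, 1)),
        "a1m": np.tile(w1, (n, 1)),
        "a2c": np.tile(w2, (n, 1)),
        "a2m": np.tile(w2, (n, 1)),
    }


def fuse_pairs(
    params: FusionParams,
    circ_codes: np.ndarray,
    mi_codes: np.ndarray,
    circ_struct: np.ndarray,
    mi_struct: np.ndarray,
    return_cache: bool = False,
):
    """Forward fusion of a batch of pairs into N_output (n x 2(seq+struct)).

    With ``return_cache=True`` also returns the intermediates needed by
    :func:`fuse_backward`.
    """
    circ_codes = np.atleast_2d(circ_codes)
    mi_codes = np.atleast_2d(mi_codes)
    circ_struct = np.atleast_2d(circ_struct)
    mi_struct = np.atleast_2d(mi_struct)
    n = circ_codes.shape[0]
    if not (mi_codes.shape[0] == circ_struct.shape[0] == mi_struct.shape[0] == n):
        raise ValueError("pair feature blocks have mismatched sample counts")
    if circ_codes.shape[1] != params.seq_dim or mi_codes.shape[1] != params.seq_dim:
        raise ValueError("sequence-code dimension mismatch")
    if circ_struct.shape[1] != params.struct_dim or mi_struct.shape[1] != params.struct_dim:
        raise ValueError("structural-vector dimension mismatch")

    if params.mode == "static":
        w = _static_weights(params, n)
        a1c, a1m = w["a1c"], w["a1m"]
    else:
        a1c = attention_weights(circ_codes, params.stage1_circ)
        a1m = attention_weights(mi_codes, params.stage1_mi)
    c_circ = np.hstack([circ_codes * a1c, circ_struct])
    c_mi = np.hstack([mi_codes * a1m, mi_struct])
    if params.mode == "static":
        a2c, a2m = w["a2c"], w["a2m"]
    else:
        a2c = attention_weights(c_circ, params.stage2_circ)
        a2m = attention_weights(c_mi, params.stage2_mi)
    fused = np.hstack([c_circ * a2c, c_mi * a2m])
    if not return_cache:
        return fused
    cache = {
        "x1c": circ_codes,
        "x1m": mi_codes,
        "a1c": a1c,
        "a1m": a1m,
        "c_circ": c_circ,
        "c_mi": c_mi,
        "a2c": a2c,
        "a2m": a2m,
    }
    return fused, cache


def fuse_pair(
    params: FusionParams,
    circ_code: np.ndarray,
    mi_code: np.ndarray,
    circ_struct: np.ndarray,
    mi_struct: np.ndarray,
) -> np.ndarray:
    """Fuse a single pair; returns the 1-D N_output vector of dim 2(64+H)."""
    return fuse_pairs(params, circ_code, mi_code, circ_struct, mi_struct)[0]


def _attn_backward(
    grad_out: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray,
    stage: AttentionStage,
):
    """Backward through y = X * softmax(X W + b).

    Returns (grad_X, grad_W, grad_b).
    """
    g = grad_out * X  # upstream into the softmax output
    dot = (g * weights).sum(axis=1, keepdims=True)
    d_logits = weights * (g - dot)
    grad_X = grad_out * weights + d_logits @ stage.weight.T
    grad_W = X.T @ d_logits
    grad_b = d_logits.sum(axis=0)
    return grad_X, grad_W, grad_b


def fuse_backward(params: FusionParams, cache: dict, grad_fused: np.ndarray) -> dict:
    """Gradients of the four attention heads given d(loss)/d(N_output).

    Input feature blocks are frozen upstream, so only parameter gradients
    are returned (keys: s1c_W, s1c_b, s1m_W, s1m_b, s2c_W, s2c_b, s2m_W,
    s2m_b).  Static mode has no trainable fusion parameters.
    """
    if params.mode == "static":
        return {}
    d_seq = params.seq_dim
    d_cat = d_seq + params.struct_dim
    g_circ, g_mi = grad_fused[:, :d_cat], grad_fused[:, d_cat:]
    grad_c_circ, g2c_W, g2c_b = _attn_backward(
        g_circ, cache["c_circ"], cache["a2c"], params.stage2_circ
    )
    grad_c_mi, g2m_W, g2m_b = _attn_backward(
        g_mi, cache["c_mi"], cache["a2m"], params.stage2_mi
    )
    _, g1c_W, g1c_b = _attn_backward(
        grad_c_circ[:, :d_seq], cache["x1c"], cache["a1c"], params.stage1_circ
    )
    _, g1m_W, g1m_b = _attn_backward(
        grad_c_mi[:, :d_seq], cache["x1m"], cache["a1m"], params.stage1_mi
    )
    return {
        "s1c_W": g1c_W,
        "s1c_b": g1c_b,
        "s1m_W": g1m_W,
        "s1m_b": g1m_b,
        "s2c_W": g2c_W,
        "s2c_b": g2c_b,
        "s2m_W": g2m_W,
        "s2m_b": g2m_b,
    }


def standardize(
    F: np.ndarray,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-feature z-scoring.

    With ``stats=None`` the mean/sd are fitted on ``F`` (training data) and
    returned for reuse on held-out data.  Zero-variance features pass
    through unscaled with a warning.
    """
    F = np.asarray(F, dtype=float)
    if stats is None:
        mean = F.mean(axis=0)
        sd = F.std(axis=0)
        n_const = int((sd == 0).sum())
        if n_const:
            logger.warning("%d constant feature(s) left unscaled", n_const)
        sd = np.where(sd > 0, sd, 1.0)
        stats = (mean, sd)
    mean, sd = stats
    if F.shape[1] != mean.shape[0]:
        raise ValueError("standardization stats dimension mismatch")
    return (F - mean) / sd, stats


def mean_attention_by_block(
    params: FusionParams,
    circ_codes: np.ndarray,
    mi_codes: np.ndarray,
    circ_struct: np.ndarray,
    mi_struct: np.ndarray,
) -> dict[str, float]:
    """Mean stage-2 attention mass per feature block.

    Per branch the weights sum to 1; the combined summary averages the two
    branches and reports the mean mass on circRNA-sequence, miRNA-sequence
    and structural positions (the three sum to 1).
    """
    _, cache = fuse_pairs(
        params, circ_codes, mi_codes, circ_struct, mi_struct, return_cache=True
    )
    d_seq = params.seq_dim
    circ_seq = float(cache["a2c"][:, :d_seq].sum(axis=1).mean())
    circ_str = float(cache["a2c"][:, d_seq:].sum(axis=1).mean())
    mi_seq = float(cache["a2m"][:, :d_seq].sum(axis=1).mean())
    mi_str = float(cache["a2m"][:, d_seq:].sum(axis=1).mean())
    return {
        "circ_branch_seq": circ_seq,
        "circ_branch_struct": circ_str,
        "mi_branch_seq": mi_seq,
        "mi_branch_struct": mi_str,
        "circ_seq": circ_seq / 2.0,
        "mi_seq": mi_seq / 2.0,
        "struct": (circ_str + mi_str) / 2.0,
    }
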