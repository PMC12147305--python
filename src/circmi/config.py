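"""Run configuration: every tunable of the pipeline in one dataclass.

A serialized config plus a seed reproduces a run bit-for-bit in
single-threaded mode.  Unknown keys are rejected on load.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # sequence embedding
    kmer_k: int = 3
    embed_dim: int = 64
    window: int = 5
    k_neg: int = 5
    sg_epochs: int = 5
    sg_lr: float = 0.025
    noise_exponent: float = 0.75
    pool_max_tokens: int = 64  # P: padded/truncated token count per sequence
    pooling: str = "mean"
    subword: bool = False
    # graph embedding
    grarep_orders: int = 4  # K
    grarep_rank: int = 16  # d_k; final structural dim H = K * d_k
    grarep_lambda: float = 1.0
    # stacked autoencoder
    sae_sizes: tuple[int, ...] = (256, 128, 64)
    sae_epochs: int = 20
    sae_lr: float = 1e-3
    sae_batch: int = 128
    sae_val_frac: float = 0.10
    sae_patience: int = 3
    # fusion + classifier
    hidden: int = 100
    l2: float = 1e-4
    lr: float = 1e-3
    max_iter: int = 5000
    batch_size: int | None = 128
    early_stopping: bool = False
    val_frac: float = 0.125  # 1/8 of the train pool = 10% overall at 5 folds
    patience: int = 200
    attn_lr_scale: float = 0.01
    fusion_mode: str = "attention"
    fusion_ratios: tuple[float, float] = (1.0, 1.0)
    threshold: float = 0.5
    # evaluation
    n_folds: int = 5
    neg_ratio: float = 1.0
    leakage_safe: bool = True

    @property
    def struct_dim(self) -> int:
        return self.grarep_orders * self.grarep_rank

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sae_sizes"] = list(d["sae_sizes"])
        d["fusion_ratios"] = list(d["fusion_ratios"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        if "sae_sizes" in data:
            data["sae_sizes"] = tuple(data["sae_sizes"])
        if "fusion_ratios" in data:
            data["fusion_ratios"] = tuple(data["fusion_ratios"])
        return cls(**data)
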