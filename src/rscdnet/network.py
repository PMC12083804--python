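"""RSCD-Net assembly: stem, four reconstruction-block stages, double
attention, pooling and the classification head."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import nn
from .core_blocks import PlainBottleneck, SCRBlock, SCRBlockConfig
from .double_attention import DoubleAttention
from .nn import functional as F

__all__ = [
    "NetworkConfig",
    "ModelSummary",
    "RSCDNet",
    "build_rscdnet",
    "summarize",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    num_classes: int = 36
    stage_sizes: Tuple[int, int, int, int] = (3, 4, 6, 3)
    stem_channels: int = 64
    stage_mid_channels: Tuple[int, int, int, int] = (64, 128, 256, 512)
    expansion: int = 4
    a2net_after_stage: int = 4
    use_double_attention: bool = True
    plain_blocks: bool = False
    a2_reduction: int = 4
    gate_threshold: float = 0.5
    alpha: float = 0.5
    squeeze_ratio: int = 2
    gwc_groups: int = 2
    gwc_kernel: int = 3
    input_size: int = 224

    def __post_init__(self):
        self.stage_sizes = tuple(self.stage_sizes)
        self.stage_mid_channels = tuple(self.stage_mid_channels)
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if len(self.stage_sizes) != 4 or any(s < 1 for s in self.stage_sizes):
            raise ValueError("stage_sizes must be four positive integers")
        if len(self.stage_mid_channels) != 4:
            raise ValueError("stage_mid_channels must have four entries")
        if not 1 <= self.a2net_after_stage <= 4:
            raise ValueError("a2net_after_stage must be in 1..4")
        if self.expansion < 1 or self.stem_channels < 1 or self.input_size < 32:
            raise ValueError("invalid stem/expansion/input_size")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class ModelSummary:
    blocks_per_stage: Tuple[int, int, int, int]
    total_scr_blocks: int
    parameter_count: int
    output_dim: int
    has_double_attention: bool
    plain_blocks: bool


class _Stage(nn.Module):
    def __init__(self, blocks):
        super().__init__()
        self.blocks = blocks
        for i, b in enumerate(blocks):
            setattr(self, f"block{i}", b)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        return x


class RSCDNet(nn.Module):
    """Residual spatial/channel reconstruction network with double attention.

    Stem (7x7/2 conv, BN, ReLU, 3x3/2 max pool) -> four stages of blocks
    -> double attention -> global average pooling -> linear head.
    """

    def __init__(self, cfg: NetworkConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.stem_conv = nn.Conv2d(3, cfg.stem_channels, 7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg.stem_channels)
        self.stem_pool = nn.MaxPool2d(3, 2, 1)

        block_cls = PlainBottleneck if cfg.plain_blocks else SCRBlock
        in_ch = cfg.stem_channels
        self.stages = []
        for si, (n_blocks, mid) in enumerate(zip(cfg.stage_sizes, cfg.stage_mid_channels)):
            blocks = []
            out_ch = mid * cfg.expansion
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                bcfg = SCRBlockConfig(
                    in_channels=in_ch, mid_channels=mid, out_channels=out_ch,
                    stride=stride, alpha=cfg.alpha,
                    squeeze_ratio=cfg.squeeze_ratio, gwc_groups=cfg.gwc_groups,
                    gwc_kernel=cfg.gwc_kernel, gate_threshold=cfg.gate_threshold,
                )
                blocks.append(block_cls(bcfg, rng=rng))
                in_ch = out_ch
            stage = _Stage(blocks)
            self.stages.append(stage)
            setattr(self, f"stage{si + 1}", stage)

        self.feature_dim = in_ch
        if cfg.use_double_attention:
            attn_ch = cfg.stage_mid_channels[cfg.a2net_after_stage - 1] * cfg.expansion
            self.attention = DoubleAttention(attn_ch, reduction=cfg.a2_reduction, rng=rng)
        else:
            self.attention = None
        self.pool = nn.GlobalAvgPool2d()
        self.head = nn.Linear(self.feature_dim, cfg.num_classes, rng=rng)

    def forward(self, x):
        shape = np.shape(x)
        if len(shape) != 4 or shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got shape {shape}")
        if shape[2] != self.cfg.input_size or shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {shape[2]}x{shape[3]} (resize before the model)"
            )
        h = F.relu(self.stem_bn(self.stem_conv(x)))
        h = self.stem_pool(h)
        for si, stage in enumerate(self.stages, start=1):
            h = stage(h)
            if self.attention is not None and si == self.cfg.a2net_after_stage:
                h = self.attention(h)
        return self.head(self.pool(h))


def build_rscdnet(cfg: NetworkConfig, seed: int = 0) -> RSCDNet:
    """Deterministic construction: identical seeds give identical weights."""
    return RSCDNet(cfg, rng=np.random.default_rng(seed))


def summarize(model: RSCDNet) -> ModelSummary:
    per_stage = tuple(len(stage.blocks) for stage in model.stages)
    return ModelSummary(
        blocks_per_stage=per_stage,
        total_scr_blocks=sum(per_stage),
        parameter_count=model.num_parameters(),
        output_dim=model.cfg.num_classes,
        has_double_attention=model.attention is not None,
        plain_blocks=model.cfg.plain_blocks,
    )


def save_checkpoint(model: RSCDNet, path, seed: int = 0, extra: Optional[dict] = None):
    """Weights + config + seed in one .npz archive (version tagged)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "seed": int(seed),
        "extra": extra or {},
    }
    state = model.state_dict()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[RSCDNet, NetworkConfig, int]:
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = NetworkConfig.from_dict(meta["config"])
    model = build_rscdnet(cfg, seed=meta["seed"])
    model.load_state_dict(state)
    model.eval()
    return model, cfg, meta["seed"]
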