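"""Spatial and channel reconstruction blocks.

The SCR-Block is a residual bottleneck whose middle stage replaces the
usual 3x3 convolution by two reconstruction units:

* SRU (spatial): group-normalizes the feature map, derives per-channel
  informativeness weights from the GN scale factors, thresholds a sigmoid
  of the modulated map into binary informative / non-informative masks,
  and cross-reconstructs the two masked copies across channel halves.
* CRU (channel): splits channels by a ratio ``alpha``, squeezes each part
  with a strided 1x1 convolution, transforms the rich part with grouped
  (GWC) and pointwise (PWC) convolutions and the cheap part with a
  pointwise completion, then fuses the two branches with per-channel
  softmax coefficients (selective-kernel style).

The equation-level primitives are exposed as free functions operating on
(N, C, H, W) arrays so they can be checked against index-loop oracles;
the classes wire them up with trainable weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import autograd.numpy as anp
import numpy as np

from . import nn
from .nn import functional as F

__all__ = [
    "GroupNormParams",
    "GateMasks",
    "SCRBlockConfig",
    "group_normalize",
    "informativeness_weights",
    "spatial_gate",
    "sru_reconstruct",
    "sru_forward",
    "cru_fuse",
    "default_gn_groups",
    "SRU",
    "CRU",
    "SCRBlock",
    "PlainBottleneck",
]

EXPANSION = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GroupNormParams:
    """Trainable affine + grouping hyperparameters of a GN layer."""

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5
    num_groups: int = 1

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if len(np.shape(self.gamma)) != 1 or np.shape(self.gamma) != np.shape(self.beta):
            raise ValueError("gamma and beta must be 1-d arrays of equal length")
        c = np.shape(self.gamma)[0]
        if self.num_groups < 1 or c % self.num_groups:
            raise ValueError(
                f"num_groups={self.num_groups} must divide C={c}"
            )


@dataclass
class GateMasks:
    """Complementary binary masks splitting a map into informative (w1)
    and non-informative (w2) parts."""

    w1: np.ndarray
    w2: np.ndarray
    threshold: float

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass
class SCRBlockConfig:
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1
    alpha: float = 0.5
    squeeze_ratio: int = 2
    gwc_groups: int = 2
    gwc_kernel: int = 3
    gate_threshold: float = 0.5

    def __post_init__(self):
        if min(self.in_channels, self.mid_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be positive")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        up = self.alpha * self.mid_channels
        if abs(up - round(up)) > 1e-9 or not 0 < round(up) < self.mid_channels:
            raise ValueError(
                f"alpha={self.alpha} does not split mid_channels="
                f"{self.mid_channels} into positive integers"
            )
        up = int(round(up))
        low = self.mid_channels - up
        if self.squeeze_ratio < 1 or up % self.squeeze_ratio or low % self.squeeze_ratio:
            raise ValueError(
                f"squeeze_ratio={self.squeeze_ratio} must divide both channel "
                f"groups ({up}, {low})"
            )
        if self.gwc_kernel < 1 or self.gwc_kernel % 2 == 0:
            raise ValueError("gwc_kernel must be odd and positive")
        if self.out_channels % self.mid_channels:
            raise ValueError("out_channels must be an integer multiple of mid_channels")
        if not 0 < self.gate_threshold < 1:
            raise ValueError("gate_threshold must lie in (0, 1)")

    @property
    def up_channels(self) -> int:
        return int(round(self.alpha * self.mid_channels))

    @property
    def low_channels(self) -> int:
        return self.mid_channels - self.up_channels

    @property
    def expansion(self) -> int:
        return self.out_channels // self.mid_channels


# ---------------------------------------------------------------------------
# equation-level primitives
# ---------------------------------------------------------------------------

def _check_4d(x) -> tuple[int, int, int, int]:
    shape = np.shape(x)
    if len(shape) != 4 or min(shape) < 1:
        raise ValueError(f"expected a (N, C, H, W) array, got shape {shape}")
    return shape


def group_normalize(x, params: GroupNormParams):
    """GN: per (sample, group) standardization followed by the per-channel
    affine transform gamma * xhat + beta."""
    _, c, _, _ = _check_4d(x)
    if np.shape(params.gamma)[0] != c:
        raise ValueError(
            f"gamma has length {np.shape(params.gamma)[0]} but input has C={c}"
        )
    return F.group_norm2d(x, params.gamma, params.beta, params.num_groups, params.eps)


def informativeness_weights(gamma):
    """Per-channel importance weights: each scale factor divided by the sum.

    Negative scale factors can appear after unconstrained training, in which
    case magnitudes are normalized instead so the weights stay meaningful.
    """
    from autograd.tracer import isbox

    gamma = gamma if isbox(gamma) else np.asarray(gamma, dtype=float)
    if len(np.shape(gamma)) != 1:
        raise ValueError("gamma must be a 1-d vector")
    if np.any(np.asarray(F._np_value(gamma)) < 0):
        gamma = anp.abs(gamma)
    total = anp.sum(gamma)
    if float(F._np_value(total)) == 0.0:
        raise ValueError("sum of gamma is zero; weights undefined")
    return gamma / total


def spatial_gate(x_modulated, threshold: float) -> GateMasks:
    """Binary informative/non-informative masks from a sigmoid threshold.

    A sigmoid value must strictly exceed the threshold to count as
    informative; ties fall into the non-informative mask.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    _check_4d(x_modulated)
    s = F._np_value(F.sigmoid(x_modulated))
    w1 = (np.asarray(s) > threshold).astype(float)
    return GateMasks(w1=w1, w2=1.0 - w1, threshold=threshold)


def sru_reconstruct(x, masks: GateMasks):
    """Cross-reconstruction of the masked informative/non-informative maps.

    X1w = W1*X and X2w = W2*X are each split into channel halves;
    the first half of one is summed with the second half of the other,
    and the two sums are concatenated back along channels.
    """
    _, c, _, _ = _check_4d(x)
    if c % 2:
        raise ValueError(f"channel count must be even, got C={c}")
    if np.shape(masks.w1) != np.shape(x):
        raise ValueError("mask shape does not match input shape")
    half = c // 2
    x1w = masks.w1 * x
    x2w = masks.w2 * x
    xw1 = x1w[:, :half] + x2w[:, half:]
    xw2 = x2w[:, :half] + x1w[:, half:]
    return anp.concatenate([xw1, xw2], axis=1)


def sru_forward(x, params: GroupNormParams, threshold: float = 0.5):
    """Separation + reconstruction: GN -> informativeness weighting ->
    sigmoid gate -> cross-reconstruction of the original input."""
    gn = group_normalize(x, params)
    w_gamma = informativeness_weights(params.gamma)
    modulated = anp.reshape(w_gamma, (1, -1, 1, 1)) * gn
    masks = spatial_gate(modulated, threshold)
    return sru_reconstruct(x, masks)


def cru_fuse(y1, y2):
    """Selective-kernel fusion of two congruent branches.

    Global average pooling yields per-(sample, channel) branch statistics;
    a softmax across the two branches gives convex coefficients beta1,
    beta2 which blend the branches elementwise.
    """
    if np.shape(y1) != np.shape(y2):
        raise ValueError(
            f"branch shapes differ: {np.shape(y1)} vs {np.shape(y2)}"
        )
    _check_4d(y1)
    s1 = F.global_avg_pool2d(y1)
    s2 = F.global_avg_pool2d(y2)
    stacked = anp.stack([s1, s2], axis=1)  # (N, 2, C)
    betas = F.softmax(stacked, axis=1)
    b1 = betas[:, 0][:, :, None, None]
    b2 = betas[:, 1][:, :, None, None]
    return b1 * y1 + b2 * y2


def default_gn_groups(channels: int, cap: int = 16) -> int:
    """Largest divisor of ``channels`` not exceeding ``cap``."""
    g = min(cap, channels)
    while channels % g:
        g -= 1
    return g


# ---------------------------------------------------------------------------
# trainable units
# ---------------------------------------------------------------------------

class SRU(nn.Module):
    """Spatial reconstruction unit with trainable GN affine parameters."""

    def __init__(self, channels: int, threshold: float = 0.5,
                 num_groups: Optional[int] = None, eps: float = 1e-5):
        super().__init__()
        if not 0 < threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        groups = num_groups if num_groups is not None else default_gn_groups(channels)
        self.gn = nn.GroupNorm(groups, channels, eps)
        self.threshold = threshold

    def forward(self, x):
        params = GroupNormParams(
            gamma=self.gn.weight.value, beta=self.gn.bias.value,
            eps=self.gn.eps, num_groups=self.gn.num_groups,
        )
        return sru_forward(x, params, self.threshold)


class CRU(nn.Module):
    """Channel reconstruction unit: split -> squeeze -> transform -> fuse.

    Spatial downsampling for stride-2 blocks happens in the squeeze
    convolutions so that the low branch's pass-through stays congruent
    with its pointwise completion.
    """

    def __init__(self, channels: int, alpha: float = 0.5, squeeze_ratio: int = 2,
                 gwc_groups: int = 2, gwc_kernel: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        cfg = SCRBlockConfig(
            in_channels=channels, mid_channels=channels,
            out_channels=channels * EXPANSION, stride=stride, alpha=alpha,
            squeeze_ratio=squeeze_ratio, gwc_groups=gwc_groups,
            gwc_kernel=gwc_kernel,
        )
        rng = rng or np.random.default_rng()
        self.channels = channels
        up, low = cfg.up_channels, cfg.low_channels
        up_sq, low_sq = up // squeeze_ratio, low // squeeze_ratio
        if up_sq % gwc_groups or channels % gwc_groups:
            raise ValueError(
                f"gwc_groups={gwc_groups} must divide squeezed up channels "
                f"({up_sq}) and output channels ({channels})"
            )
        if channels - low_sq < 1:
            raise ValueError("squeezed low branch leaves no room for completion")
        self.up_channels, self.low_channels = up, low
        self.squeeze_up = nn.Conv2d(up, up_sq, 1, stride=stride, bias=False, rng=rng)
        self.squeeze_low = nn.Conv2d(low, low_sq, 1, stride=stride, bias=False, rng=rng)
        self.bn_up = nn.BatchNorm2d(up_sq)
        self.bn_low = nn.BatchNorm2d(low_sq)
        self.gwc = nn.Conv2d(up_sq, channels, gwc_kernel,
                             padding=gwc_kernel // 2, groups=gwc_groups,
                             bias=False, rng=rng)
        self.pwc_up = nn.Conv2d(up_sq, channels, 1, bias=False, rng=rng)
        self.pwc_low = nn.Conv2d(low_sq, channels - low_sq, 1, bias=False, rng=rng)

    def split_squeeze(self, xw):
        """Route the first alpha*C channels to the up path, squeeze both."""
        _, c, _, _ = _check_4d(xw)
        if c != self.channels:
            raise ValueError(f"expected C={self.channels}, got {c}")
        up = self.bn_up(self.squeeze_up(xw[:, : self.up_channels]))
        low = self.bn_low(self.squeeze_low(xw[:, self.up_channels:]))
        return up, low

    def transform(self, up, low):
        """Rich branch: GWC + PWC; cheap branch: pointwise completion
        concatenated with the squeezed input itself."""
        y1 = self.gwc(up) + self.pwc_up(up)
        y2 = anp.concatenate([self.pwc_low(low), low], axis=1)
        return y1, y2

    def forward(self, x):
        up, low = self.split_squeeze(x)
        y1, y2 = self.transform(up, low)
        return cru_fuse(y1, y2)


class SCRBlock(nn.Module):
    """Residual bottleneck with the SRU -> CRU pair in the middle."""

    def __init__(self, cfg: SCRBlockConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        mid = cfg.mid_channels
        self.conv1 = nn.Conv2d(cfg.in_channels, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.sru = SRU(mid, threshold=cfg.gate_threshold)
        self.cru = CRU(mid, alpha=cfg.alpha, squeeze_ratio=cfg.squeeze_ratio,
                       gwc_groups=cfg.gwc_groups, gwc_kernel=cfg.gwc_kernel,
                       stride=cfg.stride, rng=rng)
        self.conv3 = nn.Conv2d(mid, cfg.out_channels, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cfg.out_channels)
        if cfg.stride == 1 and cfg.in_channels == cfg.out_channels:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cfg.in_channels, cfg.out_channels, 1,
                          stride=cfg.stride, bias=False, rng=rng),
                nn.BatchNorm2d(cfg.out_channels),
            )

    def forward(self, x):
        _, c, _, _ = _check_4d(x)
        if c != self.cfg.in_channels:
            raise ValueError(f"expected C={self.cfg.in_channels}, got {c}")
        h = F.relu(self.bn1(self.conv1(x)))
        h = self.sru(h)
        h = self.cru(h)
        h = self.bn3(self.conv3(h))
        return F.relu(h + self.shortcut(x))


class PlainBottleneck(nn.Module):
    """Standard 1x1 -> 3x3 -> 1x1 bottleneck (ablation stand-in)."""

    def __init__(self, cfg: SCRBlockConfig, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        mid = cfg.mid_channels
        self.conv1 = nn.Conv2d(cfg.in_channels, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=cfg.stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cfg.out_channels, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cfg.out_channels)
        if cfg.stride == 1 and cfg.in_channels == cfg.out_channels:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cfg.in_channels, cfg.out_channels, 1,
                          stride=cfg.stride, bias=False, rng=rng),
                nn.BatchNorm2d(cfg.out_channels),
            )

    def forward(self, x):
        h = F.relu(self.bn1(self.conv1(x)))
        h = F.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        return F.relu(h + self.shortcut(x))
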