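"""Double attention: bilinear gathering of global descriptors followed by
per-position soft distribution.

``gather`` pools features from all positions into k global descriptors
using attention maps that are softmax-normalized over positions;
``distribute`` hands each position a convex combination of those
descriptors using weights softmax-normalized over the k descriptors.
"""

from __future__ import annotations

from typing import Optional

import autograd.numpy as anp
import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["gather", "distribute", "DoubleAttention"]


def gather(a, b):
    """Sum of per-position outer products: ``g = a @ b.T``.

    a: (m, n) position features; b: (k, n) attention maps (rows are
    distributions over the n positions).  Returns an (m, k) matrix whose
    column j is the global feature pooled by attention map j.
    """
    if len(np.shape(a)) != 2 or len(np.shape(b)) != 2:
        raise ValueError("gather expects 2-d matrices")
    if np.shape(a)[1] != np.shape(b)[1]:
        raise ValueError(
            f"position extents differ: {np.shape(a)[1]} vs {np.shape(b)[1]}"
        )
    return anp.dot(a, anp.transpose(b))


def distribute(g, v):
    """Per-position convex combination of global descriptors: ``z = g @ v``.

    g: (m, k) descriptors; v: (k, n) selection weights whose columns sum
    to 1 over k.  Returns (m, n).
    """
    if len(np.shape(g)) != 2 or len(np.shape(v)) != 2:
        raise ValueError("distribute expects 2-d matrices")
    if np.shape(g)[1] != np.shape(v)[0]:
        raise ValueError(
            f"descriptor extents differ: {np.shape(g)[1]} vs {np.shape(v)[0]}"
        )
    return anp.dot(g, v)


class DoubleAttention(nn.Module):
    """Batched double-attention module with 1x1 convolution feature maps.

    phi/theta/rho produce the position features, gathering attentions and
    distribution weights respectively; a final 1x1 projection returns to
    the input width and is added residually.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if channels % reduction or channels // reduction < 1:
            raise ValueError(
                f"reduction={reduction} must divide channels={channels}"
            )
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.inner = channels // reduction  # m = k
        self.phi = nn.Conv2d(channels, self.inner, 1, bias=False, rng=rng)
        self.theta = nn.Conv2d(channels, self.inner, 1, bias=False, rng=rng)
        self.rho = nn.Conv2d(channels, self.inner, 1, bias=False, rng=rng)
        self.proj = nn.Conv2d(self.inner, channels, 1, bias=False, rng=rng)

    def attention_triple(self, x):
        """(A, B, V) with B row-stochastic over positions and V
        column-stochastic over the k descriptors."""
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected C={self.channels}, got {c}")
        flat = (n, self.inner, h * w)
        a = anp.reshape(self.phi(x), flat)
        b = F.softmax(anp.reshape(self.theta(x), flat), axis=2)
        v = F.softmax(anp.reshape(self.rho(x), flat), axis=1)
        return a, b, v

    def forward(self, x):
        n, c, h, w = x.shape
        a, b, v = self.attention_triple(x)
        g = anp.einsum("nmp,nkp->nmk", a, b)
        z = anp.einsum("nmk,nkp->nmp", g, v)
        z = anp.reshape(z, (n, self.inner, h, w))
        return x + self.proj(z)
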