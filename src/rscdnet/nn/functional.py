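"""Differentiable array operations used by the layer classes.

Everything here is written against :mod:`autograd.numpy` so that the same
code path serves plain-numpy inference and reverse-mode gradient
computation during training.  Inputs follow the (N, C, H, W) layout.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval as _np_value  # unbox traced arrays

__all__ = [
    "relu",
    "sigmoid",
    "softmax",
    "log_softmax",
    "linear",
    "conv2d",
    "max_pool2d",
    "global_avg_pool2d",
    "batch_norm2d",
    "group_norm2d",
    "cross_entropy",
    "conv_output_size",
]


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    # split by sign for overflow safety; anp.where evaluates both branches,
    # so clip the exponent arguments instead
    z = anp.clip(x, -60.0, 60.0)
    return 1.0 / (1.0 + anp.exp(-z))


def softmax(x, axis=-1):
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(shifted)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    shifted = x - anp.max(x, axis=axis, keepdims=True)
    return shifted - anp.log(anp.sum(anp.exp(shifted), axis=axis, keepdims=True))


def linear(x, weight, bias=None):
    """x: (N, in), weight: (out, in), bias: (out,)."""
    y = anp.dot(x, weight.T)
    if bias is not None:
        y = y + bias
    return y


def conv_output_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def _window_indices(h: int, w: int, kh: int, kw: int, stride: int, padding: int):
    """Gather indices mapping a padded (H, W) plane to (KH, KW, OH, OW)."""
    oh = conv_output_size(h, kh, stride, padding)
    ow = conv_output_size(w, kw, stride, padding)
    i0 = np.arange(kh)[:, None, None, None]
    j0 = np.arange(kw)[None, :, None, None]
    i1 = stride * np.arange(oh)[None, None, :, None]
    j1 = stride * np.arange(ow)[None, None, None, :]
    ii = np.broadcast_to(i0 + i1, (kh, kw, oh, ow))
    jj = np.broadcast_to(j0 + j1, (kh, kw, oh, ow))
    return ii, jj, oh, ow


def _im2col(x, kh: int, kw: int, stride: int, padding: int):
    """(N, C, H, W) -> patches (N, C, KH, KW, OH, OW)."""
    n, c, h, w = x.shape
    if padding > 0:
        x = anp.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)), "constant")
    ii, jj, oh, ow = _window_indices(h, w, kh, kw, stride, padding)
    return x[:, :, ii, jj], oh, ow


def conv2d(x, weight, bias=None, stride=1, padding=0, groups=1):
    """2-d cross-correlation.

    x: (N, C_in, H, W); weight: (C_out, C_in // groups, KH, KW);
    bias: (C_out,) or None.  Returns (N, C_out, OH, OW).
    """
    n, c_in, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c_in % groups or c_out % groups:
        raise ValueError(f"channels ({c_in}->{c_out}) not divisible by groups={groups}")
    if c_in_g != c_in // groups:
        raise ValueError(
            f"weight expects {c_in_g * groups} input channels, got {c_in}"
        )
    patches, oh, ow = _im2col(x, kh, kw, stride, padding)
    if groups == 1:
        cols = anp.reshape(patches, (n, c_in * kh * kw, oh * ow))
        wmat = anp.reshape(weight, (c_out, c_in * kh * kw))
        out = anp.einsum("ok,nkp->nop", wmat, cols)
    else:
        cols = anp.reshape(patches, (n, groups, c_in_g * kh * kw, oh * ow))
        wmat = anp.reshape(weight, (groups, c_out // groups, c_in_g * kh * kw))
        out = anp.einsum("gok,ngkp->ngop", wmat, cols)
        out = anp.reshape(out, (n, c_out, oh * ow))
    out = anp.reshape(out, (n, c_out, oh, ow))
    if bias is not None:
        out = out + anp.reshape(bias, (1, c_out, 1, 1))
    return out


def max_pool2d(x, kernel=3, stride=2, padding=1):
    n, c, h, w = x.shape
    if padding > 0:
        pad_val = -np.inf
        x = anp.pad(
            x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            "constant", constant_values=pad_val,
        )
    ii, jj, oh, ow = _window_indices(h, w, kernel, kernel, stride, padding)
    patches = x[:, :, ii, jj]  # (N, C, K, K, OH, OW)
    return anp.max(anp.max(patches, axis=2), axis=2)


def global_avg_pool2d(x):
    """(N, C, H, W) -> (N, C)."""
    return anp.mean(x, axis=(2, 3))


def batch_norm2d(x, gamma, beta, mean, var, eps=1e-5):
    """Normalize with the supplied statistics (batch or running)."""
    inv = 1.0 / anp.sqrt(var + eps)
    out = (x - anp.reshape(mean, (1, -1, 1, 1))) * anp.reshape(inv, (1, -1, 1, 1))
    return out * anp.reshape(gamma, (1, -1, 1, 1)) + anp.reshape(beta, (1, -1, 1, 1))


def group_norm2d(x, gamma, beta, num_groups, eps=1e-5):
    """Group normalization over (channels-in-group, H, W) per sample."""
    n, c, h, w = x.shape
    if c % num_groups:
        raise ValueError(f"C={c} not divisible by num_groups={num_groups}")
    xg = anp.reshape(x, (n, num_groups, c // num_groups, h, w))
    mu = anp.mean(xg, axis=(2, 3, 4), keepdims=True)
    var = anp.mean((xg - mu) ** 2, axis=(2, 3, 4), keepdims=True)
    xhat = anp.reshape((xg - mu) / anp.sqrt(var + eps), (n, c, h, w))
    return xhat * anp.reshape(gamma, (1, -1, 1, 1)) + anp.reshape(beta, (1, -1, 1, 1))


def cross_entropy(logits, labels):
    """Mean negative log-likelihood. logits: (N, K); labels: int (N,)."""
    logp = log_softmax(logits, axis=1)
    n = logits.shape[0]
    return -anp.mean(logp[np.arange(n), np.asarray(labels)])
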