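"""Gradient plumbing and the AdamW optimizer."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from autograd import value_and_grad

from .module import Module, Parameter

__all__ = ["loss_and_gradients", "AdamW"]


def loss_and_gradients(model: Module, loss_fn: Callable[[], object]):
    """Evaluate ``loss_fn`` and differentiate it w.r.t. all model parameters.

    ``loss_fn`` is a closure that runs the model forward and returns a scalar
    loss; the model must read parameters through ``Parameter.value`` so that
    the traced overrides installed here are picked up.
    Returns ``(loss_value, grads)`` with grads ordered as ``model.parameters()``.
    """
    params = model.parameters()

    def wrapped(values):
        for p, v in zip(params, values):
            p._override = v
        return loss_fn()

    try:
        loss, grads = value_and_grad(wrapped)([p.data for p in params])
    finally:
        for p in params:
            p._override = None
    return loss, grads


class AdamW:
    """AdamW: Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05, decay_mask: Sequence[bool] | None = None):
        if lr < 0 or weight_decay < 0:
            raise ValueError("lr and weight_decay must be non-negative")
        self.params = list(params)
        if decay_mask is None:
            # conventional exemption: 1-d parameters (norm scales, biases)
            decay_mask = [p.data.ndim > 1 for p in self.params]
        if len(decay_mask) != len(self.params):
            raise ValueError("decay_mask length does not match parameter list")
        self.decay_mask = list(decay_mask)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = np.asarray(g)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            wd = self.weight_decay if self.decay_mask[i] else 0.0
            # decoupled decay: shrink weights directly, not through the moments
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + wd * p.data
            )
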