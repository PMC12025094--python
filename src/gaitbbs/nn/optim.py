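"""Adam optimiser over the layer kit's parameter dictionaries."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    """Adam with the conventional defaults (beta1 0.9, beta2 0.999, eps 1e-8).

    ``layers`` is a flat list; each layer's ``params``/``grads`` dicts are
    updated in place so snapshots taken with ``copy.deepcopy`` of the params
    remain valid restore points.
    """

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def zero_grad(self) -> None:
        for ly in self.layers:
            ly.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
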