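"""Root-mean-squared-propagation optimizer and the WGAN weight clip."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class RMSProp:
    """Classic RMSProp: v <- decay*v + (1-decay)*g^2; p <- p - lr*g/(sqrt(v)+eps)."""

    def __init__(self, net: Sequential, lr: float = 2e-4, decay: float = 0.9,
                 eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self._v: dict[str, np.ndarray] = {
            name: np.zeros_like(p) for name, p, _ in net.named_parameters()
        }

    def step(self) -> None:
        for name, p, g in self.net.named_parameters():
            v = self._v[name]
            v *= self.decay
            v += (1.0 - self.decay) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def clip_weights(net: Sequential, bound: float) -> None:
    """Clamp every trainable parameter to [-bound, bound] (WGAN critic constraint)."""
    for _, p, _ in net.named_parameters():
        np.clip(p, -bound, bound, out=p)


def max_abs_weight(net: Sequential) -> float:
    return max(float(np.max(np.abs(p))) for _, p, _ in net.named_parameters())
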