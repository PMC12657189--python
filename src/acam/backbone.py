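"""Small reference classifier backbone and the Adam optimizer.

The backbone is a deliberately compact stand-in for the large decision
networks the contrast block is normally plugged into: three strided 3x3
convolution blocks with ReLU, global average pooling, and a linear head.
It exists so the block, the training modes and the metrics can be
exercised end to end on one CPU; it is not meant to be competitive.
"""

from __future__ import annotations

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .nets import _Net

__all__ = ["ConvBackbone", "Adam"]


class ConvBackbone(_Net):
    """conv(C->w, s2) -> conv(w->2w, s2) -> conv(2w->2w, s2) -> GAP -> FC."""

    def __init__(self, in_channels: int, n_classes: int, width: int = 16, seed: int = 0):
        super().__init__()
        if in_channels < 1 or n_classes < 1:
            raise ValueError("in_channels and n_classes must be >= 1")
        self.in_channels = int(in_channels)
        self.n_classes = int(n_classes)
        self.width = int(width)
        rng = np.random.default_rng(seed)

        def he(shape):
            fan_in = int(np.prod(shape[1:]))
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        w = self.width
        self.w1 = self._add("w1", he((w, in_channels, 3, 3)))
        self.b1 = self._add("b1", np.zeros(w))
        self.w2 = self._add("w2", he((2 * w, w, 3, 3)))
        self.b2 = self._add("b2", np.zeros(2 * w))
        self.w3 = self._add("w3", he((2 * w, 2 * w, 3, 3)))
        self.b3 = self._add("b3", np.zeros(2 * w))
        self.w4 = self._add("w4", he((n_classes, 2 * w)))
        self.b4 = self._add("b4", np.zeros(n_classes))

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) -> (N, n_classes) logits."""
        h = ag.relu(ag.conv2d(x, self.w1, self.b1, stride=2, padding=1))
        h = ag.relu(ag.conv2d(h, self.w2, self.b2, stride=2, padding=1))
        h = ag.relu(ag.conv2d(h, self.w3, self.b3, stride=2, padding=1))
        h = h.mean(axis=(2, 3))
        return ag.linear(h, self.w4, self.b4)


class Adam:
    """Adaptive-moment optimizer over a list of nets; skips frozen nets."""

    def __init__(self, nets, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.nets = list(nets)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for net in self.nets:
            for p in net.parameters().values():
                p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for net in self.nets:
            if net.frozen:
                continue
            for p in net.parameters().values():
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                m = self._m[key] = self.b1 * self._m[key] + (1 - self.b1) * p.grad
                v = self._v[key] = self.b2 * self._v[key] + (1 - self.b2) * p.grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
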