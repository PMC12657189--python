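"""The shallow texture decision network and the assembled ACAM block.

Contrast prediction depends on local, high-frequency texture rather than
semantics, so the decision network is deliberately shallow: two strided
3x3 convolutions (1 -> 8 -> 16 channels, stride 2, ReLU), global average
pooling, and a single fully connected layer emitting K pre-activations.
Under the defaults this is well under 5,000 parameters. The assembled
block maps an image to K pre-activations, squashes them into gains in
(1, 3), and expands the image into the K x H x W view stack — all
differentiably, so the block trains jointly with any downstream
classifier or separately against recorded clinician gains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .contrast import expand_views, map_to_contrast, validate_image

__all__ = [
    "TextureNet",
    "AcamConfig",
    "texture_forward",
    "generate_contrasts",
    "acam_forward",
    "fuse_input_adapter",
    "numerical_gradient_check",
]

FUSION_MODES = ("channel-stack", "logit-mean")


@dataclass
class AcamConfig:
    """Module configuration: view count, fusion mode, working resolution."""

    n_views: int = 10
    fusion: str = "channel-stack"
    input_size: int = 64

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}, got {self.fusion!r}")


class _Net:
    """Base: a named, ordered collection of parameter tensors."""

    frozen: bool = False

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def _add(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> dict[str, Tensor]:
        return self._params

    def freeze(self) -> "_Net":
        """Forbid parameter updates; optimizers skip frozen nets. Idempotent."""
        self.frozen = True
        return self

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self._params.values())

    def checksum(self) -> bytes:
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self._params):
            h.update(name.encode())
            h.update(self._params[name].data.tobytes())
        return h.digest()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self._params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


def _conv_init(rng: np.random.Generator, shape: tuple[int, ...], scale: float = 0.05) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class TextureNet(_Net):
    """Shallow texture network: conv(1->8, s2) -> conv(8->16, s2) -> GAP -> FC(16->K).

    Seeded uniform init with zero biases. The convolution weights use a
    moderate scale (0.5) so texture features have usable magnitude from
    the start; the head weights are small (0.05) so the initial
    pre-activations sit near 0 and the initial gains near 2, the middle
    of the (1, 3) range.
    """

    def __init__(self, n_views: int = 10, seed: int = 0):
        super().__init__()
        if n_views < 1:
            raise ValueError("n_views must be >= 1")
        self.n_views = int(n_views)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.w1 = self._add("w1", _conv_init(rng, (8, 1, 3, 3), scale=0.5))
        self.b1 = self._add("b1", np.zeros(8))
        self.w2 = self._add("w2", _conv_init(rng, (16, 8, 3, 3), scale=0.5))
        self.b2 = self._add("b2", np.zeros(16))
        self.w3 = self._add("w3", _conv_init(rng, (self.n_views, 16)))
        self.b3 = self._add("b3", np.zeros(self.n_views))

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, K) pre-activations."""
        h = ag.relu(ag.conv2d(x, self.w1, self.b1, stride=2, padding=1))
        h = ag.relu(ag.conv2d(h, self.w2, self.b2, stride=2, padding=1))
        h = h.mean(axis=(2, 3))  # global average pooling
        return ag.linear(h, self.w3, self.b3)

    # -- serialization (plain JSON; the net is tiny) ---------------------
    def save(self, path) -> None:
        payload = {
            "kind": "texture_net",
            "n_views": self.n_views,
            "seed": self.seed,
            "frozen": self.frozen,
            "params": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TextureNet":
        payload = json.loads(Path(path).read_text())
        net = cls(n_views=payload["n_views"], seed=payload["seed"])
        net.load_state_dict({k: np.asarray(v) for k, v in payload["params"].items()})
        net.frozen = bool(payload.get("frozen", False))
        return net


def _as_batch(img) -> Tensor:
    """Lift a 2-D image or (N, 1, H, W) batch to a batched tensor."""
    if isinstance(img, Tensor):
        return img if img.data.ndim == 4 else Tensor(img.data[None, None])
    img = validate_image(img)
    return Tensor(img[None, None])


def texture_forward(img, net: TextureNet) -> np.ndarray:
    """Run the decision network on one image; returns K pre-activations."""
    out = net.forward(_as_batch(img))
    return out.data[0].copy()


def generate_contrasts(img, net: TextureNet) -> np.ndarray:
    """Predict the K adaptive gains for one image; all values lie in (1, 3)."""
    return map_to_contrast(texture_forward(img, net))


def acam_forward(img, net: TextureNet):
    """Full block: image -> gains -> K x H x W view stack.

    Numpy input gives a numpy stack; Tensor input of shape (N, 1, H, W)
    gives a differentiable (N, K, H, W) tensor with gradients flowing to
    both the pixels and the network parameters.
    """
    if isinstance(img, Tensor):
        pre = net.forward(img)
        gains = map_to_contrast(pre)
        return expand_views(img, gains)
    img = validate_image(img)
    return expand_views(img, generate_contrasts(img, net))


def fuse_input_adapter(n_views: int, in_channels: int, mode: str = "channel-stack") -> int:
    """Resolve the channel count a backbone must accept for a fusion mode.

    channel-stack feeds the whole K-view stack as a K-channel image, so
    the backbone's first layer must take ``n_views`` channels; logit-mean
    runs the backbone once per view (single channel) and averages the
    class scores.
    """
    if mode not in FUSION_MODES:
        raise ValueError(f"fusion must be one of {FUSION_MODES}, got {mode!r}")
    required = n_views if mode == "channel-stack" else 1
    if in_channels != required:
        raise ValueError(
            f"backbone accepts {in_channels} input channels but {mode} fusion of "
            f"{n_views} views requires {required}"
        )
    return required


def numerical_gradient_check(
    img: np.ndarray,
    net: TextureNet,
    eps: float = 1e-4,
    n_samples: int = 20,
    seed: int = 0,
) -> float:
    """Compare analytic and central-finite-difference gradients of a probe loss.

    The probe loss is the sum of squared view-stack pixels. A random
    sample of network parameters and image pixels is perturbed by
    ``+-eps``; returns the maximum relative discrepancy between the
    analytic gradient and (L(+eps) - L(-eps)) / (2 eps). All arithmetic
    is float64.
    """
    if not (1e-6 <= eps <= 1e-3):
        raise ValueError("eps must lie in [1e-6, 1e-3]")
    img = validate_image(img)
    rng = np.random.default_rng(seed)

    def loss_value() -> float:
        stack = acam_forward(img, net)
        return float((stack**2).sum())

    # analytic pass
    x = Tensor(img[None, None], requires_grad=True)
    for t in net.parameters().values():
        t.zero_grad()
    stack = acam_forward(x, net)
    (stack * stack).sum().backward()

    worst = 0.0
    # parameter coordinates
    for name, t in net.parameters().items():
        flat = t.data.reshape(-1)
        gflat = t.grad.reshape(-1)
        idx = rng.choice(flat.size, size=min(n_samples, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_value()
            flat[i] = orig - eps
            lm = loss_value()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(gflat[i]), 1e-8)
            worst = max(worst, abs(num - gflat[i]) / denom)
    # pixel coordinates
    gimg = x.grad[0, 0]
    flat_img = img.reshape(-1)
    idx = rng.choice(flat_img.size, size=min(n_samples, flat_img.size), replace=False)
    for i in idx:
        orig = flat_img[i]
        flat_img[i] = orig + eps
        lp = loss_value()
        flat_img[i] = orig - eps
        lm = loss_value()
        flat_img[i] = orig
        num = (lp - lm) / (2 * eps)
        ana = gimg.reshape(-1)[i]
        denom = max(abs(num), abs(ana), 1e-8)
        worst = max(worst, abs(num - ana) / denom)
    return worst
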