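"""Training harness: plain / RCJ / joint-ACAM / two-stage-ACAM modes.

Thin, manifest-aware wrappers over the estimators in
:mod:`acam.estimators`. The documented full-scale defaults follow the
study configuration (batch size 64, 20 epochs, learning rate 1e-3, Adam,
cross-entropy); fixture-scale runs override epochs and sample counts.

The two-stage workflow:

1. ``train_stage1`` fits the texture network so its mean predicted gain
   regresses onto each sample's recorded ideal restoring gain alpha*;
2. ``freeze_generator`` locks those parameters;
3. ``train_classifier(mode="acam_two_stage", ...)`` trains only the
   backbone on top of the frozen contrast generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .estimators import MODES, AcamContrastRegressor, AcamImageClassifier
from .contrast import apply_contrast
from .nets import TextureNet
from .phantoms import DatasetManifest

__all__ = [
    "TrainConfig",
    "Stage1Config",
    "ModelBundle",
    "reference_backbone",
    "rcj_augment",
    "train_stage1",
    "freeze_generator",
    "train_classifier",
]


@dataclass
class TrainConfig:
    """Classifier-stage hyperparameters (full-scale defaults)."""

    mode: str = "plain"
    batch_size: int = 64
    epochs: int = 20
    lr: float = 1e-3
    n_views: int = 10
    fusion: str = "channel-stack"
    image_size: int = 64
    backbone_width: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.batch_size < 1 or self.epochs < 1 or self.lr <= 0:
            raise ValueError("batch_size, epochs and lr must be positive")


@dataclass
class Stage1Config:
    """Supervised contrast-generation hyperparameters (MSE regression)."""

    epochs: int = 80
    batch_size: int = 64
    lr: float = 1e-2
    n_views: int = 10
    image_size: int = 64


@dataclass
class ModelBundle:
    """A trained classifier plus its provenance."""

    classifier: AcamImageClassifier
    mode: str
    config: dict
    history: list = field(default_factory=list)
    seed: int = 0

    @property
    def texture_net(self) -> TextureNet | None:
        return self.classifier.texture_net_


def reference_backbone(in_channels: int, n_classes: int, width: int = 16, seed: int = 0):
    """Construct the small reference convolutional classifier."""
    from .backbone import ConvBackbone

    return ConvBackbone(in_channels, n_classes, width=width, seed=seed)


def rcj_augment(img: np.ndarray, rng: np.random.Generator, low: float = 1.0, high: float = 3.0):
    """Random contrast jittering: one gain drawn uniformly from [low, high]."""
    return apply_contrast(img, float(rng.uniform(low, high)))


def _split_arrays(images: np.ndarray, manifest: DatasetManifest, split: str):
    idx = manifest.split_index(split)
    if idx.size == 0:
        raise ValueError(f"manifest has no samples in split {split!r}")
    df = manifest.records.iloc[idx]
    return images[idx], df["class"].to_numpy(), df


def train_stage1(
    images: np.ndarray, manifest: DatasetManifest, cfg: Stage1Config | None = None, seed: int = 0
) -> tuple[TextureNet, list[float]]:
    """Stage 1: fit the texture net against recorded restoring gains.

    Trains on the manifest's train split; returns the trained network
    and the per-epoch loss history. Deterministic under a fixed seed.
    """
    cfg = cfg or Stage1Config()
    if "alpha_star" not in manifest.records.columns:
        raise ValueError("manifest lacks recorded restoring gains (alpha_star)")
    x, _, df = _split_arrays(images, manifest, "train")
    reg = AcamContrastRegressor(
        n_views=cfg.n_views,
        image_size=cfg.image_size,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        seed=seed,
    ).fit(x, df["alpha_star"].to_numpy())
    return reg.net_, reg.loss_history_


def freeze_generator(net: TextureNet) -> TextureNet:
    """Lock the contrast generator; optimizers leave it bit-identical."""
    return net.freeze()


def train_classifier(
    images: np.ndarray,
    manifest: DatasetManifest,
    cfg: TrainConfig,
    acam_params: TextureNet | None = None,
) -> ModelBundle:
    """Train the backbone in the configured mode and log train/test accuracy."""
    if cfg.mode == "acam_two_stage" and acam_params is None:
        raise ValueError("acam_two_stage mode requires stage-1 texture-net parameters")
    if cfg.mode in ("plain", "rcj") and acam_params is not None:
        raise ValueError(f"mode {cfg.mode!r} does not accept texture-net parameters")
    x_train, y_train, _ = _split_arrays(images, manifest, "train")
    x_test, y_test, _ = _split_arrays(images, manifest, "test")
    clf = AcamImageClassifier(
        mode=cfg.mode,
        n_views=cfg.n_views,
        fusion=cfg.fusion,
        image_size=cfg.image_size,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.lr,
        backbone_width=cfg.backbone_width,
        contrast_net=acam_params,
        seed=cfg.seed,
    )
    clf.fit(x_train, y_train, eval_set=(x_test, y_test))
    return ModelBundle(
        classifier=clf, mode=cfg.mode, config=asdict(cfg), history=clf.history_, seed=cfg.seed
    )
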