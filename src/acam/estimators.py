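"""Scikit-learn-style estimators wrapping the contrast block and backbone.

`AcamContrastRegressor` is the stage-1 model: it trains the shallow
texture network so that the mean of its K predicted gains regresses onto
a recorded ideal restoring gain (a clinician's logged contrast
adjustment). `AcamImageClassifier` trains the reference backbone in one
of four modes:

- ``plain``          — backbone on the raw grayscale image;
- ``rcj``            — random contrast jittering augmentation, one gain
                       drawn uniformly from [1, 3] per image per epoch;
- ``acam``           — the adaptive block trained jointly with the
                       backbone (default integration);
- ``acam_two_stage`` — a pre-trained, frozen texture network feeds the
                       backbone (the record-then-freeze workflow).

Both estimators follow the sklearn contract: hyperparameters in
``__init__``, state learned in ``fit`` stored with trailing underscores,
``get_params``/``set_params`` inherited from ``BaseEstimator``. Inputs
are image batches of shape (n_samples, H, W) on an arbitrary intensity
scale; images are resampled to ``image_size`` if needed. All training is
serial, float64 and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _autograd as ag
from ._autograd import Tensor
from .backbone import Adam, ConvBackbone
from .contrast import apply_contrast, map_to_contrast
from .nets import FUSION_MODES, TextureNet, fuse_input_adapter

__all__ = ["AcamContrastRegressor", "AcamImageClassifier", "ContrastViewTransformer"]

MODES = ("plain", "rcj", "acam", "acam_two_stage")


def _check_images(X, image_size: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError(f"expected image batch of shape (n, H, W), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("images contain non-finite values")
    if X.shape[1:] != (image_size, image_size):
        from skimage.transform import resize

        X = np.stack(
            [resize(im, (image_size, image_size), anti_aliasing=True) for im in X]
        )
    return X


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AcamContrastRegressor(BaseEstimator, RegressorMixin):
    """Supervised contrast generation: regress mean predicted gain on alpha*.

    Minimizes the mean squared error between the mean of the K mapped
    gains and the recorded restoring gain, with Adam. ``predict`` returns
    the mean predicted gain per image, always inside (1, 3).
    """

    def __init__(
        self,
        n_views: int = 10,
        image_size: int = 64,
        epochs: int = 80,
        batch_size: int = 64,
        lr: float = 1e-2,
        seed: int = 0,
    ):
        self.n_views = n_views
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, X, y):
        X = _check_images(X, self.image_size)
        y = np.asarray(y, dtype=np.float64)
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one recorded gain per image")
        net = TextureNet(n_views=self.n_views, seed=self.seed)
        opt = Adam([net], lr=self.lr)
        rng = np.random.default_rng(self.seed)
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(X.shape[0])
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = Tensor(X[idx][:, None])
                gains = map_to_contrast(net.forward(xb))  # (B, K)
                diff = gains.mean(axis=1) - Tensor(y[idx])
                loss = (diff * diff).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            history.append(epoch_loss / X.shape[0])
        self.net_ = net
        self.loss_history_ = history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_images(X, self.image_size)
        out = self.net_.forward(Tensor(X[:, None]))
        return map_to_contrast(out.data).mean(axis=1)


class AcamImageClassifier(BaseEstimator, ClassifierMixin):
    """Grayscale image classifier with optional adaptive contrast front end."""

    def __init__(
        self,
        mode: str = "acam",
        n_views: int = 10,
        fusion: str = "channel-stack",
        image_size: int = 64,
        epochs: int = 10,
        batch_size: int = 64,
        lr: float = 1e-3,
        backbone_width: int = 16,
        rcj_range: tuple[float, float] = (1.0, 3.0),
        contrast_net: TextureNet | None = None,
        seed: int = 0,
    ):
        self.mode = mode
        self.n_views = n_views
        self.fusion = fusion
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.backbone_width = backbone_width
        self.rcj_range = rcj_range
        self.contrast_net = contrast_net
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _forward(self, xb: Tensor, texture: TextureNet | None) -> Tensor:
        if texture is None:
            return self.backbone_.forward(xb)
        from .nets import acam_forward

        views = acam_forward(xb, texture)  # (B, K, H, W)
        if self.fusion == "channel-stack":
            return self.backbone_.forward(views)
        b, k = views.shape[0], views.shape[1]
        per_view = views.reshape(b * k, 1, views.shape[2], views.shape[3])
        logits = self.backbone_.forward(per_view)
        return logits.reshape(b, k, logits.shape[1]).mean(axis=1)

    def fit(self, X, y, eval_set=None):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}")
        X = _check_images(X, self.image_size)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)

        texture: TextureNet | None = None
        if self.mode == "acam":
            if self.contrast_net is not None:
                # joint training updates the net; work on a copy so the
                # estimator does not mutate its constructor argument
                texture = TextureNet(self.contrast_net.n_views, seed=self.contrast_net.seed)
                texture.load_state_dict(self.contrast_net.state_dict())
                texture.frozen = self.contrast_net.frozen
            else:
                texture = TextureNet(n_views=self.n_views, seed=self.seed + 17)
        elif self.mode == "acam_two_stage":
            if self.contrast_net is None:
                raise ValueError("acam_two_stage mode requires a pre-trained contrast_net")
            if not self.contrast_net.frozen:
                raise ValueError("acam_two_stage mode requires the contrast_net to be frozen")
            texture = self.contrast_net
        elif self.contrast_net is not None:
            raise ValueError(f"mode {self.mode!r} does not accept a contrast_net")

        in_channels = 1
        if texture is not None:
            proposed = texture.n_views if self.fusion == "channel-stack" else 1
            in_channels = fuse_input_adapter(texture.n_views, proposed, self.fusion)
        self.backbone_ = ConvBackbone(
            in_channels, n_classes, width=self.backbone_width, seed=self.seed + 1
        )
        self.texture_net_ = texture
        nets = [self.backbone_] + ([texture] if texture is not None else [])
        opt = Adam(nets, lr=self.lr)
        rng = np.random.default_rng(self.seed)

        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(X.shape[0])
            epoch_loss, correct = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = X[idx]
                if self.mode == "rcj":
                    lo, hi = self.rcj_range
                    batch = np.stack(
                        [apply_contrast(im, rng.uniform(lo, hi)) for im in batch]
                    )
                xb = Tensor(batch[:, None])
                logits = self._forward(xb, texture)
                loss = ag.cross_entropy(logits, y_idx[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                correct += int((logits.data.argmax(axis=1) == y_idx[idx]).sum())
            entry = {
                "epoch": epoch,
                "train_loss": epoch_loss / X.shape[0],
                "train_acc": correct / X.shape[0],
            }
            if eval_set is not None:
                entry["test_acc"] = float(self.score(*eval_set))
            history.append(entry)
        self.history_ = history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _check_images(X, self.image_size)
        logits = np.empty((X.shape[0], len(self.classes_)))
        bs = max(self.batch_size, 1)
        for start in range(0, X.shape[0], bs):
            xb = Tensor(X[start : start + bs][:, None])
            logits[start : start + bs] = self._forward(xb, self.texture_net_).data
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]


class ContrastViewTransformer(BaseEstimator):
    """Expose a (fitted or fresh) texture network as a batch transformer.

    ``transform`` maps (n, H, W) images to the (n, K, H, W) stack of
    adaptively contrast-adjusted views — the plug-and-play front end for
    any downstream model. ``fit`` is a no-op unless no network was given,
    in which case a freshly initialized one (gains near 2) is created.
    """

    def __init__(self, contrast_net: TextureNet | None = None, n_views: int = 10,
                 image_size: int = 64, seed: int = 0):
        self.contrast_net = contrast_net
        self.n_views = n_views
        self.image_size = image_size
        self.seed = seed

    def fit(self, X=None, y=None):
        self.net_ = self.contrast_net or TextureNet(n_views=self.n_views, seed=self.seed)
        return self

    def transform(self, X) -> np.ndarray:
        from .nets import acam_forward

        if not hasattr(self, "net_"):
            self.fit()
        X = _check_images(X, self.image_size)
        return acam_forward(Tensor(X[:, None]), self.net_).data
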