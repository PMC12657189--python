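"""Seeded six-class ultrasound-like phantom generator.

Each phantom is a class-distinctive geometric scene (abdomen, femur,
cervix, thorax, brain, other) on a dark background, corrupted by fully
developed multiplicative speckle and then by an operator-style contrast
compression with gain ``g`` drawn log-uniformly from [1/3, 1]. The ideal
restoring gain ``alpha* = clamp(1/g, 1, 3)`` is recorded per sample — it
plays the role of a clinician's logged contrast adjustment and
supervises stage-1 training. Before degradation every speckled scene is
rescaled to a fixed reference contrast (standard deviation 0.20 about
its mean), emulating calibrated acoustic output across acquisitions;
this makes the applied compression identifiable from image statistics.

Class proportions default to the fetal-plane study roster
(711, 1040, 1626, 1718, 3092, 4213) and samples are split 70/30 into
train and test, stratified per class. Everything is reproducible
bit-for-bit from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .contrast import apply_contrast, validate_image

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_CLASS_WEIGHTS",
    "PhantomSpec",
    "DatasetManifest",
    "largest_remainder",
    "render_phantom",
    "apply_speckle",
    "degrade_contrast",
    "generate_arrays",
    "generate_dataset",
]

CLASS_NAMES = ("abdomen", "femur", "cervix", "thorax", "brain", "other")

#: per-class sample counts of the reference fetal-plane roster
DEFAULT_CLASS_WEIGHTS = (711, 1040, 1626, 1718, 3092, 4213)

#: reference contrast (std about the mean) of a calibrated clean acquisition
REFERENCE_STD = 0.20


@dataclass
class PhantomSpec:
    """Generation parameters for one synthetic dataset."""

    n_samples: int = 600
    image_size: int = 64
    class_proportions: tuple[float, ...] = tuple(
        w / sum(DEFAULT_CLASS_WEIGHTS) for w in DEFAULT_CLASS_WEIGHTS
    )
    speckle_strength: float = 0.5
    gain_range: tuple[float, float] = (1.0 / 3.0, 1.0)
    #: optional override applied to test-split samples only (robustness studies)
    test_gain_range: tuple[float, float] | None = None
    brightness_jitter: float = 0.05
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        lo, hi = self.gain_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("gain range must lie inside (0, 1]")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")


@dataclass
class DatasetManifest:
    """Sample records plus the provenance needed to regenerate them."""

    records: pd.DataFrame  # columns: path, class, g, alpha_star, split, seed
    seed: int
    class_counts: tuple[int, ...] = field(default=())

    def split_index(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.records["split"].to_numpy() == split)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path)
        counts = tuple(
            int((df["class"] == c).sum()) for c in range(int(df["class"].max()) + 1)
        )
        return cls(records=df, seed=int(df["seed"].iloc[0]), class_counts=counts)


def largest_remainder(total: int, proportions) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``proportions``.

    Floors the exact quotas, then hands the remaining units to the
    largest fractional remainders (ties broken by lower class index).
    Deterministic and exactly proportion-faithful in sum.
    """
    props = np.asarray(proportions, dtype=np.float64)
    if total < 0 or np.any(props < 0):
        raise ValueError("total and proportions must be nonnegative")
    quotas = total * props / props.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.lexsort((np.arange(props.size), -(quotas - counts)))
    counts[order[:remainder]] += 1
    return counts


# -- scene rendering ------------------------------------------------------


def _grid(n: int):
    y, x = np.mgrid[0:n, 0:n]
    return (y - (n - 1) / 2) / n, (x - (n - 1) / 2) / n


def _rot(y, x, theta):
    c, s = np.cos(theta), np.sin(theta)
    return c * y - s * x, s * y + c * x


def render_phantom(class_id: int, rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Render one clean (noise-free) class-distinctive scene in [0, 1].

    Geometry per class: 0 ellipse with inner dark disc (abdomen), 1 bright
    elongated bar (femur), 2 V-shaped wedge (cervix), 3 ellipse with two
    lobes (thorax), 4 ellipse with bright midline (brain), 5 random blob
    field (other). Position, size and orientation jitter come from ``rng``.
    """
    if not 0 <= class_id < len(CLASS_NAMES):
        raise ValueError(f"class_id must be in 0..{len(CLASS_NAMES) - 1}, got {class_id}")
    n = spec.image_size
    y, x = _grid(n)
    img = np.full((n, n), 0.08)
    cy, cx = rng.uniform(-0.08, 0.08, size=2)
    theta = rng.uniform(-0.4, 0.4)
    yy, xx = _rot(y - cy, x - cx, theta)

    if class_id == 0:  # abdomen: bright elliptical wall, dark stomach bubble
        a, b = rng.uniform(0.28, 0.36), rng.uniform(0.22, 0.30)
        r = np.sqrt((yy / a) ** 2 + (xx / b) ** 2)
        img += 0.55 * (r < 1.0)
        img += 0.25 * ((r > 0.82) & (r < 1.0))  # echogenic wall
        br = np.sqrt(((yy - 0.08) / (0.35 * a)) ** 2 + ((xx - 0.08) / (0.35 * b)) ** 2)
        img[br < 1.0] = 0.10
    elif class_id == 1:  # femur: thin bright bar, aspect ratio > 3
        half_len = rng.uniform(0.30, 0.38)
        half_w = rng.uniform(0.030, 0.045)
        img += 0.85 * ((np.abs(xx) < half_len) & (np.abs(yy) < half_w))
    elif class_id == 2:  # cervix: V-shaped wedge of two bright limbs
        for sign in (-1.0, 1.0):
            ly, lx = _rot(yy + 0.18, xx, sign * rng.uniform(0.45, 0.60))
            img += 0.6 * ((np.abs(lx) < 0.05) & (ly > -0.05) & (ly < 0.45))
        img = np.clip(img, 0, 0.75)
    elif class_id == 3:  # thorax: ellipse with two bright lobes (lungs)
        a, b = rng.uniform(0.30, 0.38), rng.uniform(0.26, 0.34)
        r = np.sqrt((yy / a) ** 2 + (xx / b) ** 2)
        img += 0.35 * (r < 1.0)
        for sx in (-0.5, 0.5):
            lr = np.sqrt(((yy) / (0.45 * a)) ** 2 + ((xx - sx * b) / (0.38 * b)) ** 2)
            img += 0.35 * (lr < 1.0)
    elif class_id == 4:  # brain: ellipse with bright midline echo
        a, b = rng.uniform(0.30, 0.38), rng.uniform(0.24, 0.32)
        r = np.sqrt((yy / a) ** 2 + (xx / b) ** 2)
        img += 0.45 * (r < 1.0)
        img += 0.40 * ((np.abs(xx) < 0.025) & (np.abs(yy) < 0.9 * a))
    else:  # other: random blob field
        for _ in range(rng.integers(4, 8)):
            by, bx = rng.uniform(-0.3, 0.3, size=2)
            rad = rng.uniform(0.05, 0.14)
            amp = rng.uniform(0.2, 0.6)
            img += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * rad**2)))

    img = ndimage.gaussian_filter(img, sigma=0.8)
    return np.clip(img, 0.0, 1.0)


def apply_speckle(img: np.ndarray, rng: np.random.Generator, strength: float) -> np.ndarray:
    """Blend fully developed multiplicative speckle into an image.

    The speckle field ``s`` is unit-mean exponential (intensity speckle);
    the output is ``(1 - strength) * img + strength * img * s``, floored
    at 0. ``strength`` 0 leaves the image untouched; 1 is pure speckle.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("speckle strength must lie in [0, 1]")
    img = validate_image(img)
    if strength == 0.0:
        return img.copy()
    s = rng.exponential(scale=1.0, size=img.shape)
    return np.maximum((1.0 - strength) * img + strength * img * s, 0.0)


def degrade_contrast(
    img: np.ndarray, g: float, jitter: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Compress contrast by gain ``g`` and jitter brightness.

    Applies the mean-preserving linear transform with gain ``g`` in
    (0, 1], then adds one uniform brightness offset in [-jitter, jitter].
    Returns the degraded image and the ideal restoring gain
    ``alpha* = clamp(1/g, 1, 3)``; for g in [1/3, 1] and zero jitter,
    restoring with alpha* inverts the degradation exactly.
    """
    if not (np.isfinite(g) and 0.0 < g <= 1.0):
        raise ValueError(f"degradation gain must lie in (0, 1], got {g!r}")
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    out = apply_contrast(img, g)
    if jitter > 0:
        out = out + rng.uniform(-jitter, jitter)
    alpha_star = float(np.clip(1.0 / g, 1.0, 3.0))
    return out, alpha_star


def _standardize_contrast(img: np.ndarray, target_std: float = REFERENCE_STD) -> np.ndarray:
    """Rescale deviations about the mean to a fixed reference std."""
    mu, sd = img.mean(), img.std()
    if sd < 1e-8:
        return img.copy()
    return (img - mu) * (target_std / sd) + mu


def generate_arrays(spec: PhantomSpec):
    """Generate the full dataset in memory.

    Returns ``(clean, degraded, manifest)`` where ``clean`` holds the
    speckled, contrast-calibrated scenes (the stage-1 restoration
    targets), ``degraded`` the observed images, and ``manifest`` the
    per-sample records (class, g, alpha*, split). Deterministic in
    ``spec.seed``: per-sample generators are spawned from one seed
    sequence, so the pixel stream of one sample is independent of how
    many others exist.
    """
    counts = largest_remainder(spec.n_samples, spec.class_proportions)
    master = np.random.SeedSequence(spec.seed)
    split_rng = np.random.default_rng(master.spawn(1)[0])

    labels, splits = [], []
    for cls, cnt in enumerate(counts):
        n_train = int(round(spec.train_fraction * cnt))
        tags = np.array(["train"] * n_train + ["test"] * (cnt - n_train))
        split_rng.shuffle(tags)
        labels.extend([cls] * cnt)
        splits.extend(tags.tolist())
    labels = np.array(labels)
    splits = np.array(splits)

    n = len(labels)
    size = spec.image_size
    clean = np.empty((n, size, size))
    degraded = np.empty((n, size, size))
    gains = np.empty(n)
    alphas = np.empty(n)
    children = master.spawn(1 + n)[1:]
    log_lo, log_hi = np.log(spec.gain_range[0]), np.log(spec.gain_range[1])
    if spec.test_gain_range is not None:
        tlo, thi = spec.test_gain_range
        tlog = (np.log(tlo), np.log(thi))
    for i in range(n):
        rng = np.random.default_rng(children[i])
        scene = render_phantom(int(labels[i]), rng, spec)
        scene = apply_speckle(scene, rng, spec.speckle_strength)
        scene = _standardize_contrast(scene)
        if spec.test_gain_range is not None and splits[i] == "test":
            g = float(np.exp(rng.uniform(*tlog)))
        else:
            g = float(np.exp(rng.uniform(log_lo, log_hi)))
        degraded[i], alphas[i] = degrade_contrast(scene, g, spec.brightness_jitter, rng)
        clean[i] = scene
        gains[i] = g

    records = pd.DataFrame(
        {
            "path": [f"{s}/{c}/{i:05d}.png" for i, (s, c) in enumerate(zip(splits, labels))],
            "class": labels,
            "g": gains,
            "alpha_star": alphas,
            "split": splits,
            "seed": spec.seed,
        }
    )
    manifest = DatasetManifest(records=records, seed=spec.seed, class_counts=tuple(counts))
    return clean, degraded, manifest


def generate_dataset(spec: PhantomSpec, out_dir) -> DatasetManifest:
    """Render the dataset to ``<out_dir>/<split>/<class>/<id>.png`` + manifest.csv.

    Images are written as 8-bit PNGs (display-clipped to [0, 1]); the
    manifest records the float-exact gain and alpha* per sample.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    _, degraded, manifest = generate_arrays(spec)
    for i, row in manifest.records.iterrows():
        p = out_dir / row["path"]
        p.parent.mkdir(parents=True, exist_ok=True)
        img8 = (np.clip(degraded[i], 0.0, 1.0) * 255.0).round().astype(np.uint8)
        iio.imwrite(p, img8)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_images(root, manifest: DatasetManifest) -> np.ndarray:
    """Read the manifest's PNGs back as float images on [0, 1]."""
    import imageio.v3 as iio

    root = Path(root)
    return np.stack(
        [np.asarray(iio.imread(root / p), dtype=np.float64) / 255.0 for p in manifest.records["path"]]
    )
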