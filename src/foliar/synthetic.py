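"""Seeded synthetic fixtures: leaf-like disease images and structured feature matrices.

Two generators make the whole pipeline testable without external datasets:

* :func:`make_leaf_images` renders class-conditional leaf images — a textured
  background, an elliptical leaf, and class-specific low-contrast disease
  blobs — optionally degraded with a constant-transmission haze
  ``I = t * J + (1 - t) * L`` with ``L = (1, 1, 1)``.
* :func:`make_feature_matrix` draws feature matrices with known
  informative / redundant / noise column structure, emulating the fused
  deep-feature matrices that the wrapper feature selection consumes.

Both are bit-reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .training import FeatureMatrix

__all__ = [
    "LeafImageSpec",
    "FeatureSpec",
    "make_leaf_images",
    "make_feature_matrix",
    "make_dehaze_scene",
    "add_haze",
]


@dataclass
class LeafImageSpec:
    """Parameters of the leaf-image generator.

    disease_contrast scales how far blob color departs from leaf color, in
    absolute intensity units; 0.1 is a genuinely low-contrast symptom.
    haze_t, when set, applies the haze model forward with that constant
    transmission and white atmospheric light.
    """

    classes: int = 4
    per_class: int = 10
    side: int = 64
    disease_contrast: float = 0.3
    haze_t: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("classes must be >= 2")
        if self.per_class < 4:
            raise ValueError("per_class must be >= 4")
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if not 0.0 < self.disease_contrast <= 1.0:
            raise ValueError("disease_contrast must be in (0, 1]")


@dataclass
class FeatureSpec:
    """Parameters of the structured feature-matrix generator.

    effect_size is the class-mean separation of each informative column in
    units of its noise standard deviation; redundant columns are noisy linear
    copies (copy-noise SD ``copy_noise``) of randomly chosen informative
    columns; noise columns carry no class signal.
    """

    n: int = 300
    classes: int = 3
    informative: int = 5
    redundant: int = 10
    noise: int = 25
    effect_size: float = 1.0
    copy_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.informative < 1:
            raise ValueError("informative must be >= 1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.n < self.classes:
            raise ValueError("need at least one sample per class")

    @property
    def total_columns(self) -> int:
        return self.informative + self.redundant + self.noise


# class -> (blob count, blob radius as fraction of side, blob RGB direction)
_CLASS_BLOBS = [
    (3, 0.06, (0.65, 0.45, 0.10)),   # rust-like spots
    (6, 0.04, (0.85, 0.85, 0.80)),   # powdery patches
    (2, 0.10, (0.25, 0.15, 0.10)),   # dark rot lesions
    (5, 0.05, (0.60, 0.65, 0.20)),   # chlorotic specks
    (4, 0.07, (0.30, 0.30, 0.45)),   # water-soaked lesions
    (7, 0.035, (0.75, 0.55, 0.35)),  # scab-like flecks
]


def add_haze(image: np.ndarray, t: float) -> np.ndarray:
    """Apply the haze model forward with constant transmission and white light."""
    return np.clip(t * image + (1.0 - t), 0.0, 1.0)


def _smooth_noise(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma)
    span = f.max() - f.min()
    return (f - f.min()) / span if span > 0 else np.zeros_like(f)


def make_leaf_images(
    spec: LeafImageSpec,
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Render class-conditional leaf images.

    Returns ``(images, labels, masks)``: H x W x 3 float arrays in [0, 1],
    integer labels in ``[0, classes)``, and boolean ground-truth disease masks.
    Classes differ only in their blob statistics (count, size, hue) so the
    classification signal is the disease region, not the leaf silhouette.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    labels = np.repeat(np.arange(spec.classes), spec.per_class)

    for label in labels:
        n_blobs, r_frac, blob_rgb = _CLASS_BLOBS[label % len(_CLASS_BLOBS)]
        # soil-like textured background
        tex = _smooth_noise(rng, s, sigma=3.0)
        img = np.stack(
            [0.35 + 0.15 * tex, 0.28 + 0.12 * tex, 0.20 + 0.10 * tex], axis=-1
        )
        # elliptical leaf, slightly jittered pose
        cy, cx = s / 2 + rng.uniform(-2, 2), s / 2 + rng.uniform(-2, 2)
        ry, rx = s * rng.uniform(0.30, 0.38), s * rng.uniform(0.22, 0.30)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        leaf = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        vein = _smooth_noise(rng, s, sigma=2.0)
        leaf_color = np.stack(
            [0.18 + 0.10 * vein, 0.45 + 0.15 * vein, 0.15 + 0.08 * vein], axis=-1
        )
        img = np.where(leaf[..., None], leaf_color, img)

        # class-specific disease blobs, blended at the requested contrast
        mask = np.zeros((s, s), dtype=bool)
        inside = np.argwhere(leaf)
        if len(inside):
            for _ in range(n_blobs):
                by, bx = inside[rng.integers(len(inside))]
                r = max(2.0, r_frac * s * rng.uniform(0.7, 1.3))
                blob = (yy - by) ** 2 + (xx - bx) ** 2 <= r**2
                blob &= leaf
                mask |= blob
                target = np.asarray(blob_rgb)
                img[blob] = img[blob] + spec.disease_contrast * (target - img[blob])
        img = np.clip(img, 0.0, 1.0)
        if spec.haze_t is not None:
            img = add_haze(img, spec.haze_t)
        images.append(img)
        masks.append(mask)

    return images, labels, masks


def make_dehaze_scene(side: int = 96, seed: int = 0) -> np.ndarray:
    """Synthetic scene satisfying the dark-channel prior, for dehazing tests.

    A smooth fully-saturated color field (every pixel has one zero channel,
    so the scene dark channel is identically zero) with a small white
    highlight that anchors the atmospheric-light estimate once haze is
    applied.  Outdoor hazy scenes supply both ingredients (shadows/saturated
    surfaces and a sky region); the leaf-image fixtures deliberately do not,
    which is why they are not used to test haze inversion.
    """
    rng = np.random.default_rng(seed)
    hue = _smooth_noise(rng, side, sigma=6.0) * 6.0  # HSV hue sector in [0, 6)
    value = 0.3 + 0.6 * _smooth_noise(rng, side, sigma=8.0)
    h_i = np.floor(hue).astype(int) % 6
    f = hue - np.floor(hue)
    p = np.zeros_like(value)
    q = value * (1.0 - f)
    t = value * f
    channels = {
        0: (value, t, p), 1: (q, value, p), 2: (p, value, t),
        3: (p, q, value), 4: (t, p, value), 5: (value, p, q),
    }
    img = np.zeros((side, side, 3))
    for sector, (r, g, b) in channels.items():
        mask = h_i == sector
        img[mask, 0], img[mask, 1], img[mask, 2] = r[mask], g[mask], b[mask]
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = rng.integers(side // 5, side - side // 5, 2)
    # large enough that a 15 x 15 dark-channel window fits fully inside it
    highlight = (yy - cy) ** 2 + (xx - cx) ** 2 <= (side // 6) ** 2
    img[highlight] = 1.0
    return np.clip(img, 0.0, 1.0)


def make_feature_matrix(spec: FeatureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw a feature matrix with known informative / redundant / noise columns.

    Returns the :class:`~foliar.training.FeatureMatrix` (column tags
    ``informative``, ``redundant:<source>``, ``noise``) and the index array of
    the informative-or-redundant (signal-bearing) columns.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(spec.classes), spec.n // spec.classes)
    labels = np.concatenate(
        [labels, rng.integers(0, spec.classes, spec.n - len(labels))]
    )
    rng.shuffle(labels)

    m = spec.total_columns
    X = np.empty((spec.n, m))
    tags: list[str] = []
    # class means on a standardized ladder, one noise-SD apart per effect_size
    offsets = np.arange(spec.classes) - (spec.classes - 1) / 2.0
    info_idx = np.arange(spec.informative)
    for j in info_idx:
        sign = 1.0 if j % 2 == 0 else -1.0
        means = sign * spec.effect_size * offsets
        X[:, j] = means[labels] + rng.standard_normal(spec.n)
        tags.append("informative")
    sources = rng.integers(0, spec.informative, spec.redundant)
    for k, src in enumerate(sources):
        j = spec.informative + k
        X[:, j] = X[:, src] + spec.copy_noise * rng.standard_normal(spec.n)
        tags.append(f"redundant:{src}")
    for k in range(spec.noise):
        j = spec.informative + spec.redundant + k
        X[:, j] = rng.standard_normal(spec.n)
        tags.append("noise")

    signal = np.arange(spec.informative + spec.redundant)
    return FeatureMatrix(X, labels.astype(int), tags), signal
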