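"""Autoencoder class balancing: expand every class to a fixed target count.

A small convolutional autoencoder is trained per class on the (enhanced)
images at a working resolution of 64 x 64; new images are decoder outputs of
noise-perturbed latent codes.  Source images are allocated passes round-robin
— for a class of 64 expanded to 1000 each source yields 15 or 16 variants,
and doubling a class gives every image exactly two passes — so the output
count is exact, mirroring the balanced after-augmentation column of the
reference datasets (1000 per class).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn

__all__ = ["AugmentConfig", "Autoencoder", "train_autoencoder", "generate_class", "pass_allocation"]


@dataclass
class AugmentConfig:
    target_per_class: int = 1000
    latent_dim: int = 64
    epochs: int = 20
    noise_scale: float = 0.1
    seed: int = 0
    image_side: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.image_side % 4:
            raise ValueError("image_side must be divisible by 4")


class Autoencoder:
    """Conv encoder (two stride-2 convs) to a dense latent; mirrored decoder.

    Decoder output passes through a sigmoid, so generated images are always
    in [0, 1] at the configured spatial size.
    """

    def __init__(self, cfg: AugmentConfig, rng: np.random.Generator):
        side = cfg.image_side
        self.cfg = cfg
        self.bottleneck_hw = side // 4
        flat = 16 * self.bottleneck_hw**2
        self.encoder = [
            nn.Conv2D(3, 8, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.Conv2D(8, 16, 3, stride=2, rng=rng),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(flat, cfg.latent_dim, rng=rng),
        ]
        self.decoder = [
            nn.Dense(cfg.latent_dim, flat, rng=rng),
            nn.ReLU(),
            # reshape handled inline
            nn.Upsample2D(2),
            nn.Conv2D(16, 8, 3, rng=rng),
            nn.ReLU(),
            nn.Upsample2D(2),
            nn.Conv2D(8, 3, 3, rng=rng),
            nn.Sigmoid(),
        ]

    def _layers(self):
        return self.encoder + self.decoder

    def encode(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(images, dtype=float).transpose(0, 3, 1, 2)
        for layer in self.encoder:
            x = layer.forward(x, train=train)
        return x

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        x = z
        for i, layer in enumerate(self.decoder):
            x = layer.forward(x, train=train)
            if i == 1:  # after the dense + relu, restore the spatial block
                hw = self.bottleneck_hw
                x = x.reshape(len(x), 16, hw, hw)
        return x.transpose(0, 2, 3, 1)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(images))

    def _train_step(self, x: np.ndarray, opt: nn.Adam) -> float:
        z = self.encode(x, train=True)
        out = self.decode(z, train=True)
        target = np.asarray(x, dtype=float)
        diff = out - target
        loss = float((diff**2).mean())
        dy = (2.0 / diff.size) * diff
        d = dy.transpose(0, 3, 1, 2)
        for i, layer in enumerate(reversed(self.decoder)):
            d = layer.backward(d)
            if len(self.decoder) - 1 - i == 2:  # below the reshape point
                d = d.reshape(len(d), -1)
        for layer in reversed(self.encoder):
            d = layer.backward(d)
        opt.step()
        return loss

    def loss(self, x: np.ndarray) -> float:
        return float(((self.reconstruct(x) - np.asarray(x, dtype=float)) ** 2).mean())


def _prepare(images: list[np.ndarray], side: int) -> np.ndarray:
    out = []
    for img in images:
        img = np.asarray(img, dtype=float)
        if img.shape[:2] != (side, side):
            img = resize(img, (side, side, 3), order=1, anti_aliasing=False)
        out.append(np.clip(img, 0.0, 1.0))
    return np.stack(out)


def train_autoencoder(
    images: list[np.ndarray], cfg: AugmentConfig | None = None
) -> tuple[Autoencoder, list[float]]:
    """Train the class autoencoder; returns it with the per-epoch loss curve.

    The loss curve is the full-training-set reconstruction MSE evaluated
    after each epoch (entry 0 is the pre-training loss), so the decrease
    from first to last entry is the learning contract.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or AugmentConfig()
    if len(images) < 2:
        raise ValueError("need at least 2 images to train the autoencoder")
    x = _prepare(images, cfg.image_side)
    rng = np.random.default_rng(cfg.seed)
    ae = Autoencoder(cfg, rng)
    opt = nn.Adam([l for l in ae._layers() if l.params], lr=cfg.learning_rate)
    losses = [ae.loss(x)]
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), cfg.batch_size):
            ae._train_step(x[order[start : start + cfg.batch_size]], opt)
        losses.append(ae.loss(x))
    return ae, losses


def pass_allocation(n_sources: int, target: int) -> np.ndarray:
    """Round-robin pass counts per source image summing exactly to ``target``."""
    base, extra = divmod(target, n_sources)
    counts = np.full(n_sources, base, dtype=int)
    counts[:extra] += 1
    return counts


def generate_class(
    images: list[np.ndarray],
    cfg: AugmentConfig | None = None,
    autoencoder: Autoencoder | None = None,
) -> list[np.ndarray]:
    """Expand one class to exactly ``cfg.target_per_class`` generated images.

    Each source image receives its allocated number of passes; every pass
    decodes a latent code perturbed with isotropic Gaussian noise of SD
    ``cfg.noise_scale`` (zero noise reproduces the plain reconstruction).
    Fixed seed gives a byte-identical output set.
    """
    cfg = cfg or AugmentConfig()
    if cfg.target_per_class < len(images):
        raise ValueError("target_per_class must be >= class size")
    if autoencoder is None:
        autoencoder, _ = train_autoencoder(images, cfg)
    x = _prepare(images, cfg.image_side)
    z = autoencoder.encode(x)
    rng = np.random.default_rng(cfg.seed + 1)
    counts = pass_allocation(len(images), cfg.target_per_class)
    out: list[np.ndarray] = []
    for i, c in enumerate(counts):
        for _ in range(c):
            zi = z[i] + cfg.noise_scale * rng.standard_normal(z.shape[1])
            out.append(autoencoder.decode(zi[None])[0])
    return out
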