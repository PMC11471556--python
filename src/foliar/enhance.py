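"""Hybrid disease-contrast enhancement: dark-channel dehazing then bi-histogram equalization.

The haze model is ``I(X) = J(X) t(X) + L (1 - t(X))`` with observed intensity
``I``, scene radiance ``J``, atmospheric light ``L`` and transmission ``t``.
Restoration estimates ``L`` from the brightest dark-channel pixels, the
transmission from the dark channel of the ``L``-normalized image, and then
inverts the model.  The restored image is passed to a brightness-preserving
bi-histogram equalization (BiHE): the luminance histogram is Gaussian-smoothed,
partitioned at the valleys between its local maxima, each sub-histogram is
equalized independently onto its own dynamic range, and the output brightness
is normalized back to the input mean.

All images are H x W x 3 float arrays with intensities in [0, 1]; 8-bit I/O
quantizes by round-half-up.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "HazeConfig",
    "BiheConfig",
    "dark_channel",
    "estimate_atmospheric_light",
    "estimate_transmission",
    "recover_radiance",
    "dehaze",
    "bihe",
    "bihe_partition",
    "enhance",
    "load_image",
    "save_image",
    "enhance_directory",
]

# Rec. 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class HazeConfig:
    """Dehazing parameters.

    a is the printed static recovery offset (0.2); t0 the transmission floor;
    omega the haze retention factor; patch the dark-channel window side.
    static_recovery switches the recovery offset from the estimated
    atmospheric light (default, which actually inverts the haze model) to the
    static scalar ``a``.
    """

    a: float = 0.2
    t0: float = 0.1
    omega: float = 0.95
    patch: int = 15
    static_recovery: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.t0 <= 1.0:
            raise ValueError("t0 must be in (0, 1]")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must be in (0, 1]")
        if self.patch < 1 or self.patch % 2 == 0:
            raise ValueError("patch must be odd and >= 1")
        if not 0.0 <= self.a < 1.0:
            raise ValueError("a must be in [0, 1)")


@dataclass
class BiheConfig:
    bins: int = 256
    sigma: float = 3.0
    min_peak_separation: int = 8
    brightness_target: bool = True  # normalize output mean to the input mean

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.min_peak_separation < 1:
            raise ValueError("min_peak_separation must be >= 1")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    return image


def dark_channel(image: np.ndarray, patch: int = 15) -> np.ndarray:
    """Per-pixel channel minimum, then a sliding-window minimum over ``patch``."""
    image = _check_image(image)
    h, w = image.shape[:2]
    if patch % 2 == 0 or patch < 1:
        raise ValueError("patch must be odd and >= 1")
    if patch > min(h, w):
        raise ValueError("patch larger than image")
    return ndimage.minimum_filter(image.min(axis=2), size=patch, mode="nearest")


def estimate_atmospheric_light(image: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Mean color of the brightest 0.1% dark-channel pixels (at least one)."""
    image = _check_image(image)
    flat_dark = np.asarray(dark, dtype=float).ravel()
    n = max(1, int(flat_dark.size * 0.001))
    idx = np.argpartition(flat_dark, -n)[-n:]
    return image.reshape(-1, 3)[idx].mean(axis=0)


def estimate_transmission(
    image: np.ndarray, light: np.ndarray, cfg: HazeConfig | None = None
) -> np.ndarray:
    """``T = 1 - omega * dark_channel(I / L)``, clipped to [1 - omega, 1]."""
    cfg = cfg or HazeConfig()
    image = _check_image(image)
    light = np.asarray(light, dtype=float)
    if np.any(light <= 0):
        raise ValueError("atmospheric light components must be > 0")
    normalized = np.clip(image / light[None, None, :], 0.0, 1.0)
    return 1.0 - cfg.omega * dark_channel(normalized, cfg.patch)


def recover_radiance(
    image: np.ndarray,
    transmission: np.ndarray,
    offset: float | np.ndarray,
    t0: float = 0.1,
) -> np.ndarray:
    """Scene-radiance recovery ``J = (I - offset) / max(T, t0) + offset``.

    With ``offset`` equal to the atmospheric light this inverts the haze
    model; the printed static form uses the scalar ``offset = 0.2``.
    Output is clipped to [0, 1].
    """
    image = _check_image(image)
    t = np.maximum(np.asarray(transmission, dtype=float), t0)[..., None]
    offset = np.asarray(offset, dtype=float)
    if offset.ndim == 1:
        offset = offset[None, None, :]
    return np.clip((image - offset) / t + offset, 0.0, 1.0)


def dehaze(image: np.ndarray, cfg: HazeConfig | None = None) -> np.ndarray:
    """Full dark-channel-prior restoration.

    Estimates the atmospheric light and transmission map from the image, then
    recovers the radiance.  The recovery offset is the estimated light unless
    ``cfg.static_recovery`` requests the printed scalar ``cfg.a``.
    """
    cfg = cfg or HazeConfig()
    image = _check_image(image)
    dark = dark_channel(image, cfg.patch)
    light = estimate_atmospheric_light(image, dark)
    light = np.maximum(light, 1e-6)
    transmission = estimate_transmission(image, light, cfg)
    offset: float | np.ndarray = cfg.a if cfg.static_recovery else light
    return recover_radiance(image, transmission, offset, cfg.t0)


def _find_peaks(hist: np.ndarray, min_sep: int) -> list[int]:
    """Local maxima of a histogram; plateaus take the leftmost bin of a maximal run.

    Peaks closer than ``min_sep`` bins are merged keeping the higher one.
    """
    n = len(hist)
    peaks: list[int] = []
    j = 0
    while j < n:
        k = j
        while k + 1 < n and hist[k + 1] == hist[j]:
            k += 1
        left = hist[j - 1] if j > 0 else -np.inf
        right = hist[k + 1] if k + 1 < n else -np.inf
        if hist[j] > 0 and hist[j] >= left and hist[j] >= right:
            peaks.append(j)
        j = k + 1
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_sep:
            if hist[p] > hist[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def bihe_partition(luma: np.ndarray, cfg: BiheConfig | None = None) -> list[tuple[int, int]]:
    """Sub-histogram bin ranges ``[(lo, hi), ...]`` (hi exclusive) used by :func:`bihe`.

    The smoothed luminance histogram's local maxima define the modes; the
    intensity axis is split at the minimum bin between consecutive maxima.
    """
    cfg = cfg or BiheConfig()
    hist, _ = np.histogram(luma, bins=cfg.bins, range=(0.0, 1.0))
    smoothed = ndimage.gaussian_filter1d(hist.astype(float), cfg.sigma)
    peaks = _find_peaks(smoothed, cfg.min_peak_separation)
    if len(peaks) <= 1:
        return [(0, cfg.bins)]
    cuts = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        cuts.append(a + 1 + int(np.argmin(smoothed[a + 1 : b + 1])))
    bounds = [0, *cuts, cfg.bins]
    return list(zip(bounds[:-1], bounds[1:]))


def bihe(image: np.ndarray, cfg: BiheConfig | None = None) -> np.ndarray:
    """Brightness-preserving bi-histogram equalization on the luminance channel.

    Each sub-histogram is equalized independently onto its own intensity span
    (a proportional dynamic-range allocation, so a uniform single-mode
    histogram maps near-identically); chrominance is preserved by scaling RGB
    with the per-pixel luminance ratio; the output mean luminance is
    normalized back to the input mean.  A constant image is returned
    unchanged.
    """
    cfg = cfg or BiheConfig()
    image = _check_image(image)
    luma = image @ _LUMA
    if np.ptp(luma) == 0:
        return image.copy()

    segments = bihe_partition(luma, cfg)
    edges = np.linspace(0.0, 1.0, cfg.bins + 1)
    bin_idx = np.clip(np.digitize(luma, edges) - 1, 0, cfg.bins - 1)
    hist = np.bincount(bin_idx.ravel(), minlength=cfg.bins).astype(float)

    new_luma = luma.copy()
    for lo, hi in segments:
        seg_hist = hist[lo:hi]
        total = seg_hist.sum()
        if total == 0:
            continue
        cdf = np.cumsum(seg_hist) / total
        out_lo, out_hi = edges[lo], edges[hi]
        mapping = out_lo + cdf * (out_hi - out_lo)
        sel = (bin_idx >= lo) & (bin_idx < hi)
        new_luma[sel] = mapping[bin_idx[sel] - lo]

    if cfg.brightness_target:
        mean_new = new_luma.mean()
        if mean_new > 0:
            new_luma = new_luma * (luma.mean() / mean_new)

    ratio = np.divide(new_luma, luma, out=np.ones_like(luma), where=luma > 0)
    return np.clip(image * ratio[..., None], 0.0, 1.0)


def enhance(
    image: np.ndarray,
    haze_cfg: HazeConfig | None = None,
    bihe_cfg: BiheConfig | None = None,
) -> np.ndarray:
    """Hybrid enhancement: restoration first, then contrast equalization."""
    return bihe(dehaze(image, haze_cfg), bihe_cfg)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG into an H x W x 3 float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float)
    return arr / 255.0


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write [0, 1] floats as 8-bit, quantizing by round-half-up."""
    image = _check_image(image)
    q = np.floor(np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(q).save(path)


def enhance_directory(
    in_dir: str | os.PathLike,
    out_dir: str | os.PathLike,
    haze_cfg: HazeConfig | None = None,
    bihe_cfg: BiheConfig | None = None,
) -> int:
    """Mirror an input directory tree, enhancing every PNG/JPEG. Returns image count."""
    count = 0
    for root, _dirs, files in os.walk(in_dir):
        rel = os.path.relpath(root, in_dir)
        target = os.path.join(out_dir, rel) if rel != "." else str(out_dir)
        os.makedirs(target, exist_ok=True)
        for name in sorted(files):
            if not name.lower().endswith((".png", ".jpg", ".jpeg")):
                continue
            img = load_image(os.path.join(root, name))
            save_image(os.path.join(target, name), enhance(img, haze_cfg, bihe_cfg))
            count += 1
    return count
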