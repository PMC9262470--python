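"""Deterministic synthetic datasets for the full pipeline.

Real clinical photograph sets for this task are small and imbalanced
(order one hundred images, roughly 2:1 between classes).  The texture
generator emulates the statistics that matter to an oriented-filter
pipeline without any photographic content: each class is an oriented
sinusoidal grating (class-specific wavelength and orientation, with
small per-image jitter and a random phase), overlaid with dark
elliptical blobs (more and larger in the lesion class, standing in for
lesion-like structure) plus additive Gaussian noise, clipped to [0, 1].

The feature-cluster generator skips the image stage entirely: two
isotropic Gaussian clusters at a controlled separation, min-max scaled
to [0, 1] per dimension, for direct classifier tests with a known Bayes
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticConfig",
    "make_texture_dataset",
    "make_feature_clusters",
    "write_image_folder",
    "read_image_folder",
]

CLASS_A = "cancer"
CLASS_B = "noncancer"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale two-class texture dataset parameters.

    Defaults mirror a small imbalanced photograph collection: 87 lesion
    images vs 44 controls (about 2:1), 128 x 128 pixels.  The classes
    differ in grating wavelength and orientation and in blob count.
    """

    n_class_a: int = 87
    n_class_b: int = 44
    image_size: tuple[int, int] = (128, 128)
    wavelength_a: float = 4.0
    wavelength_b: float = 8.0
    theta_a: float = math.pi / 6.0
    theta_b: float = 2.0 * math.pi / 3.0
    blobs_a: int = 6
    blobs_b: int = 2
    blob_intensity: float = 0.35
    orientation_jitter: float = math.pi / 36.0  # +-5 degrees
    wavelength_jitter: float = 0.05  # +-5 percent
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class_a < 2 or self.n_class_b < 2:
            raise ValueError("need at least two images per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _grating(
    shape: tuple[int, int], wavelength: float, theta: float, phase: float
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    # projection onto the grating direction; a = columns, b = rows
    coord = cols * math.cos(theta) + rows * math.sin(theta)
    return 0.5 + 0.5 * np.sin(2.0 * math.pi * coord / wavelength + phase)


def _add_blobs(
    image: np.ndarray,
    n_blobs: int,
    intensity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = image.shape
    out = image.copy()
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w)
        ry = rng.uniform(0.04 * h, 0.12 * h)
        rx = rng.uniform(0.04 * w, 0.12 * w)
        angle = rng.uniform(0.0, math.pi)
        dy, dx = rows - cy, cols - cx
        u = dx * math.cos(angle) + dy * math.sin(angle)
        v = -dx * math.sin(angle) + dy * math.cos(angle)
        mask = np.exp(-((u / rx) ** 2 + (v / ry) ** 2))
        out -= intensity * mask  # dark elliptical blob with soft edge
    return out


def _make_image(
    config: SyntheticConfig, label: str, rng: np.random.Generator
) -> np.ndarray:
    if label == CLASS_A:
        wavelength, theta = config.wavelength_a, config.theta_a
        n_blobs = config.blobs_a
    else:
        wavelength, theta = config.wavelength_b, config.theta_b
        n_blobs = config.blobs_b
    wavelength = wavelength * (
        1.0 + rng.uniform(-config.wavelength_jitter, config.wavelength_jitter)
    )
    theta = theta + rng.uniform(-config.orientation_jitter, config.orientation_jitter)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    img = _grating(config.image_size, wavelength, theta, phase)
    img = _add_blobs(img, n_blobs, config.blob_intensity, rng)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_texture_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Generate (images, labels, ids), fully determined by ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    ids: list[str] = []
    for k in range(config.n_class_a):
        images.append(_make_image(config, CLASS_A, rng))
        labels.append(CLASS_A)
        ids.append(f"{CLASS_A}_{k:04d}")
    for k in range(config.n_class_b):
        images.append(_make_image(config, CLASS_B, rng))
        labels.append(CLASS_B)
        ids.append(f"{CLASS_B}_{k:04d}")
    return images, labels, ids


def make_feature_clusters(
    n_per_class: int,
    dim: int,
    separation: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two isotropic unit-variance Gaussian clusters, [0, 1]-scaled per dim.

    Cluster means sit at +-(separation / 2) along a fixed unit direction,
    so ``separation`` is the Mahalanobis distance between the classes
    (separation 6 means a 3-sigma margin each side; Bayes error < 0.01).
    Labels are 0 for the first cluster, 1 for the second.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    direction = np.zeros(dim)
    direction[0] = 1.0
    offset = (separation / 2.0) * direction
    X = np.vstack(
        [
            rng.normal(size=(n_per_class, dim)) - offset,
            rng.normal(size=(n_per_class, dim)) + offset,
        ]
    )
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (X - lo) / span, y


def write_image_folder(
    images: list[np.ndarray], labels: list[str], path
) -> list[Path]:
    """Write 8-bit PNGs under ``path/<label>/``; returns the file paths."""
    from PIL import Image

    path = Path(path)
    written = []
    counters: dict[str, int] = {}
    for img, label in zip(images, labels):
        sub = path / label
        sub.mkdir(parents=True, exist_ok=True)
        k = counters.get(label, 0)
        counters[label] = k + 1
        out = sub / f"{label}_{k:04d}.png"
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr).save(out)
        written.append(out)
    return written


def read_image_folder(path) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Load a class-per-subfolder PNG/JPEG tree into [0, 1] arrays."""
    from .gabor import load_image

    path = Path(path)
    images, labels, ids = [], [], []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        for f in sorted(sub.glob("*")):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            images.append(load_image(f))
            labels.append(sub.name)
            ids.append(f.stem)
    if not images:
        raise ValueError(f"no images found under {path}")
    return images, labels, ids
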