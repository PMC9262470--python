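"""2-D Gabor filter bank preprocessing.

A Gabor filter is a complex sinusoidal grating modulated by a Gaussian
envelope.  In image coordinates ``(a, b)`` (``a`` horizontal/column offset,
``b`` vertical/row offset, origin at the kernel centre) the kernel is

    G(a, b) = exp(-(a'^2 + gamma^2 b'^2) / (2 sigma^2)) * exp(i (2 pi a'/delta + psi))

with rotated coordinates a' = a cos(theta) + b sin(theta),
b' = -a sin(theta) + b cos(theta).  ``delta`` is the wavelength of the
sinusoid in pixels per cycle, ``theta`` the orientation (symmetry makes
[0, pi) sufficient), ``psi`` the phase offset, ``sigma`` the Gaussian
standard deviation and ``gamma`` the spatial aspect ratio (ellipticity of
the envelope).  ``sigma`` may instead be derived from a half-response
spatial-frequency bandwidth ``bw`` in octaves.

Filtering here means spatial correlation (not FFT) with reflect padding;
the magnitude of the complex response is used, which is phase invariant
and standard for texture enhancement and denoising of photographs before
feature extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GaborParams",
    "GaborKernel",
    "sigma_from_bandwidth",
    "gabor_kernel",
    "apply_gabor",
    "preprocess",
    "default_bank",
    "to_grayscale",
    "load_image",
    "export_kernel_text",
    "GaborPreprocessor",
]

#: ITU-R BT.601 luminance weights used for colour -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def sigma_from_bandwidth(wavelength: float, bandwidth: float) -> float:
    """Gaussian sigma (pixels) from wavelength and bandwidth in octaves.

    sigma = (delta / pi) * sqrt(ln 2 / 2) * (2^bw + 1) / (2^bw - 1)

    Narrower bandwidth (more selective filter) gives a wider envelope.
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    ratio = (2.0 ** bandwidth + 1.0) / (2.0 ** bandwidth - 1.0)
    return (wavelength / math.pi) * math.sqrt(math.log(2.0) / 2.0) * ratio


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one Gabor filter.

    Exactly one of ``sigma`` / ``bandwidth`` may be left unset; a missing
    ``sigma`` is derived via :func:`sigma_from_bandwidth`.  ``theta`` is
    normalised into [0, pi) — opposite orientations are redundant.
    """

    wavelength: float
    theta: float = 0.0
    psi: float = 0.0
    sigma: float | None = None
    gamma: float = 0.5
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.sigma is None and self.bandwidth is None:
            raise ValueError("one of sigma or bandwidth must be given")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")
        object.__setattr__(self, "theta", float(self.theta) % math.pi)

    @property
    def sigma_value(self) -> float:
        """Effective sigma, deriving it from the bandwidth when unset."""
        if self.sigma is not None:
            return float(self.sigma)
        return sigma_from_bandwidth(self.wavelength, self.bandwidth)


@dataclass(frozen=True)
class GaborKernel:
    """Sampled complex Gabor kernel: square odd-sided real/imaginary grids."""

    real_part: np.ndarray
    imag_part: np.ndarray
    size: int
    params: GaborParams

    def __post_init__(self) -> None:
        if self.real_part.shape != (self.size, self.size):
            raise ValueError("real_part shape inconsistent with size")
        if self.imag_part.shape != (self.size, self.size):
            raise ValueError("imag_part shape inconsistent with size")
        if self.size % 2 == 0:
            raise ValueError("kernel side length must be odd")


def _auto_size(params: GaborParams) -> int:
    """Smallest odd side covering +-3 sigma / max(gamma, 1) in each direction."""
    sigma = params.sigma_value
    half = int(math.ceil(3.0 * sigma / max(params.gamma, 1.0)))
    return 2 * half + 1


def gabor_kernel(params: GaborParams, size: int | str = "auto") -> GaborKernel:
    """Sample a Gabor kernel on a centred square grid.

    The centre sample sits at (a, b) = (0, 0), so its value is
    cos(psi) + i sin(psi).
    """
    if size == "auto":
        side = _auto_size(params)
    else:
        side = int(size)
        if side % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {side}")
        if side < 1:
            raise ValueError(f"kernel size must be positive, got {side}")
    half = side // 2
    # a: column offset (increases rightwards), b: row offset (increases down)
    b, a = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ct, st = math.cos(params.theta), math.sin(params.theta)
    a_rot = a * ct + b * st
    b_rot = -a * st + b * ct
    sigma = params.sigma_value
    envelope = np.exp(-(a_rot ** 2 + params.gamma ** 2 * b_rot ** 2) / (2.0 * sigma ** 2))
    phase = 2.0 * math.pi * a_rot / params.wavelength + params.psi
    return GaborKernel(
        real_part=envelope * np.cos(phase),
        imag_part=envelope * np.sin(phase),
        size=side,
        params=params,
    )


def _validate_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _magnitude_response(image: np.ndarray, kernel: GaborKernel) -> np.ndarray:
    """Un-rescaled magnitude of the complex correlation response."""
    if kernel.size > min(image.shape):
        raise ValueError(
            f"kernel side {kernel.size} exceeds image extent {min(image.shape)}"
        )
    real = ndimage.correlate(image, kernel.real_part, mode="reflect")
    imag = ndimage.correlate(image, kernel.imag_part, mode="reflect")
    return np.hypot(real, imag)


def _rescale_unit(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def apply_gabor(image: np.ndarray, kernel: GaborKernel) -> np.ndarray:
    """Magnitude response of one kernel, min-max rescaled to [0, 1].

    Spatial correlation with reflect padding; output size equals input size.
    """
    return _rescale_unit(_magnitude_response(_validate_gray(image), kernel))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an H x W x 3 image to luminance; pass 2-D input through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return image @ w
    raise ValueError(f"expected HxW or HxWx3 image, got shape {image.shape}")


def preprocess(image: np.ndarray, bank: Sequence[GaborParams]) -> np.ndarray:
    """Bank response of an image: per-pixel max magnitude, rescaled to [0, 1].

    Colour input is converted to luminance first.  The max over oriented
    bandpass responses keeps whichever orientation/frequency channel is
    locally strongest, suppressing unoriented noise.
    """
    if len(bank) == 0:
        raise ValueError("filter bank must not be empty")
    gray = _validate_gray(to_grayscale(image))
    stacked = np.stack(
        [_magnitude_response(gray, gabor_kernel(p)) for p in bank], axis=0
    )
    return _rescale_unit(stacked.max(axis=0))


def default_bank(
    wavelengths: Sequence[float] = (4.0, 8.0),
    n_orientations: int = 8,
    psi: float = 0.0,
    gamma: float = 0.5,
    bandwidth: float = 1.0,
) -> list[GaborParams]:
    """Default 16-filter bank: 8 orientations over [0, pi) x 2 wavelengths."""
    thetas = [k * math.pi / n_orientations for k in range(n_orientations)]
    return [
        GaborParams(wavelength=d, theta=t, psi=psi, gamma=gamma, bandwidth=bandwidth)
        for d in wavelengths
        for t in thetas
    ]


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG into float intensities in [0, 1].

    Integer images are normalised by their dtype maximum (8- or 16-bit).
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
    else:
        out = arr.astype(float)
    if out.ndim == 3 and out.shape[2] == 4:  # drop alpha
        out = out[:, :, :3]
    return np.clip(out, 0.0, 1.0)


def export_kernel_text(kernel: GaborKernel, path, part: str = "real") -> None:
    """Write one kernel part as a plain-text matrix, one row per line."""
    grid = kernel.real_part if part == "real" else kernel.imag_part
    np.savetxt(path, grid, fmt="%.17g")


class GaborPreprocessor:
    """Stateless sklearn-style transformer applying a Gabor bank per image.

    ``transform`` maps a sequence of images (2-D or H x W x 3 arrays) to a
    list of bank-response images in [0, 1].
    """

    def __init__(self, bank: Sequence[GaborParams] | None = None):
        self.bank = bank

    def get_params(self, deep: bool = True) -> dict:
        return {"bank": self.bank}

    def set_params(self, **params) -> "GaborPreprocessor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "GaborPreprocessor":
        self.bank_ = list(self.bank) if self.bank is not None else default_bank()
        return self

    def transform(self, X) -> list[np.ndarray]:
        if not hasattr(self, "bank_"):
            self.fit(X)
        return [preprocess(img, self.bank_) for img in X]

    def fit_transform(self, X, y=None) -> list[np.ndarray]:
        return self.fit(X, y).transform(X)
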