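"""Fixed-length feature vectors from preprocessed images.

Two extractors share one interface:

``pooled_gabor`` (default, fully offline and bitwise deterministic)
    Applies the 16-filter default Gabor bank to the resized image, pools
    {mean, standard deviation, energy} of each magnitude response over a
    4 x 4 spatial grid (16 filters x 16 cells x 3 stats = 768 raw values)
    and projects to ``output_dim`` with a seeded Gaussian random
    projection.  Energy is the mean of squared response in a cell.

``cnn_adapter`` (optional)
    Runs a pretrained NASNetMobile-class network in inference mode and
    global-average-pools the final feature map.  Requires an optional
    deep-learning runtime with downloaded weights; if absent it raises
    :class:`AdapterUnavailableError` rather than silently substituting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .gabor import GaborParams, _magnitude_response, default_bank, to_grayscale

__all__ = [
    "FeatureExtractorSpec",
    "AdapterUnavailableError",
    "extract_features",
    "pooled_gabor_features",
    "raw_pooled_gabor_statistics",
    "cnn_adapter_features",
    "projection_matrix",
    "PooledGaborFeatures",
]

POOL_GRID = 4  # 4x4 spatial pooling cells
N_STATS = 3  # mean, std, energy


class AdapterUnavailableError(RuntimeError):
    """Raised when the optional CNN backbone cannot be used."""


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Configuration of the image -> feature-vector mapping.

    ``target_size`` is the (height, width) every image is resized to
    (bilinear) before extraction; 224 x 224 mirrors the input geometry of
    mobile CNN backbones.  ``seed`` fixes the pooled-Gabor projection
    matrix, which is regenerated identically from it every run.
    """

    kind: str = "pooled_gabor"
    output_dim: int = 128
    target_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pooled_gabor", "cnn_adapter"):
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        if self.output_dim < 2:
            raise ValueError(f"output_dim must be >= 2, got {self.output_dim}")
        h, w = self.target_size
        if h < POOL_GRID or w < POOL_GRID:
            raise ValueError(f"target_size too small: {self.target_size}")


def _resize_gray(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    gray = to_grayscale(np.asarray(image, dtype=float))
    if gray.shape == tuple(target_size):
        return gray
    return resize(gray, target_size, order=1, mode="reflect", anti_aliasing=False)


def _cell_slices(extent: int) -> list[slice]:
    edges = np.linspace(0, extent, POOL_GRID + 1).round().astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(POOL_GRID)]


def raw_pooled_gabor_statistics(
    image: np.ndarray,
    target_size: tuple[int, int] = (224, 224),
    bank: Sequence[GaborParams] | None = None,
) -> np.ndarray:
    """Pre-projection statistics vector (n_filters x 16 cells x 3 stats).

    Ordering: filter-major, then cell (row-major), then (mean, std, energy).
    """
    gray = _resize_gray(image, tuple(target_size))
    bank = list(bank) if bank is not None else default_bank()
    rows = _cell_slices(gray.shape[0])
    cols = _cell_slices(gray.shape[1])
    out = np.empty(len(bank) * POOL_GRID * POOL_GRID * N_STATS)
    pos = 0
    from .gabor import gabor_kernel

    for params in bank:
        response = _magnitude_response(gray, gabor_kernel(params))
        for rs in rows:
            for cs in cols:
                cell = response[rs, cs]
                out[pos] = cell.mean()
                out[pos + 1] = cell.std()
                out[pos + 2] = np.mean(cell ** 2)
                pos += N_STATS
    return out


def projection_matrix(raw_dim: int, output_dim: int, seed: int) -> np.ndarray:
    """Seeded unit-variance Gaussian projection, regenerated per call."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((raw_dim, output_dim))


def pooled_gabor_features(
    image: np.ndarray,
    spec: FeatureExtractorSpec,
    bank: Sequence[GaborParams] | None = None,
) -> np.ndarray:
    """Deterministic offline feature vector of length ``spec.output_dim``."""
    raw = raw_pooled_gabor_statistics(image, spec.target_size, bank)
    proj = projection_matrix(raw.size, spec.output_dim, spec.seed)
    return raw @ proj


def cnn_adapter_features(image: np.ndarray, spec: FeatureExtractorSpec) -> np.ndarray:
    """Pretrained-CNN features: global-average-pooled final feature map.

    The resized image is fed as 3 channels (grayscale broadcast when
    needed); the pooled vector is truncated or zero-padded to
    ``spec.output_dim``.
    """
    try:
        from tensorflow.keras.applications import NASNetMobile  # type: ignore
        from tensorflow.keras.applications.nasnet import preprocess_input  # type: ignore
    except Exception as exc:  # pragma: no cover - runtime not installed
        raise AdapterUnavailableError(
            "cnn_adapter needs an optional deep-learning runtime with "
            "pretrained weights; install the 'cnn' extra or fall back to "
            "the pooled_gabor extractor"
        ) from exc
    gray = _resize_gray(image, (224, 224))  # pragma: no cover
    rgb = np.repeat(gray[..., None], 3, axis=2)  # pragma: no cover
    model = NASNetMobile(include_top=False, pooling="avg")  # pragma: no cover
    vec = model.predict(preprocess_input(rgb[None] * 255.0), verbose=0)[0]  # pragma: no cover
    if vec.size >= spec.output_dim:  # pragma: no cover
        return vec[: spec.output_dim].astype(float)
    return np.pad(vec.astype(float), (0, spec.output_dim - vec.size))  # pragma: no cover


def extract_features(
    image: np.ndarray,
    spec: FeatureExtractorSpec,
    bank: Sequence[GaborParams] | None = None,
) -> np.ndarray:
    """Dispatch to the configured extractor; output length = spec.output_dim."""
    if spec.kind == "pooled_gabor":
        return pooled_gabor_features(image, spec, bank)
    return cnn_adapter_features(image, spec)


class PooledGaborFeatures:
    """sklearn-style transformer: sequence of images -> (n, output_dim) matrix.

    A pure function of (image bytes, parameters); ``fit`` only freezes the
    bank and projection so the transformer composes with sklearn pipelines.
    """

    def __init__(
        self,
        output_dim: int = 128,
        target_size: tuple[int, int] = (224, 224),
        seed: int = 0,
        bank: Sequence[GaborParams] | None = None,
    ):
        self.output_dim = output_dim
        self.target_size = target_size
        self.seed = seed
        self.bank = bank

    def get_params(self, deep: bool = True) -> dict:
        return {
            "output_dim": self.output_dim,
            "target_size": self.target_size,
            "seed": self.seed,
            "bank": self.bank,
        }

    def set_params(self, **params) -> "PooledGaborFeatures":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "PooledGaborFeatures":
        self.spec_ = FeatureExtractorSpec(
            kind="pooled_gabor",
            output_dim=self.output_dim,
            target_size=tuple(self.target_size),
            seed=self.seed,
        )
        self.bank_ = list(self.bank) if self.bank is not None else default_bank()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "spec_"):
            self.fit()
        return np.vstack([pooled_gabor_features(img, self.spec_, self.bank_) for img in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)


def write_feature_csv(path, ids, labels, matrix) -> None:
    """Checkpoint a feature matrix: source_id, label, v1..vD per row."""
    import pandas as pd

    matrix = np.asarray(matrix)
    df = pd.DataFrame(matrix, columns=[f"v{i+1}" for i in range(matrix.shape[1])])
    df.insert(0, "label", list(labels))
    df.insert(0, "source_id", list(ids))
    df.to_csv(path, index=False)


def read_feature_csv(path):
    """Load a checkpointed feature matrix; returns (ids, labels, matrix)."""
    import pandas as pd

    df = pd.read_csv(path)
    return (
        df["source_id"].tolist(),
        df["label"].tolist(),
        df.iloc[:, 2:].to_numpy(dtype=float),
    )
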