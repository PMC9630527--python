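"""Static per-pixel texture features computed on the current frame.

Two features drive the pixel classifier: local Shannon entropy of the
intensity histogram in a disk neighborhood (high inside textured cells, low
in smooth background) and gradient magnitude of the smoothed frame.  The
feature set is modular: a registry maps feature names to image-valued
functions so additional features (e.g. raw intensity) can be enabled from
the run config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import EmptyClassError, ParameterError, ValidationError, DimensionError
from .labeling import LabelMap, CELL, BACKGROUND

__all__ = [
    "FeatureImages",
    "FeatureTable",
    "local_entropy",
    "local_gradient",
    "compute_features",
    "build_feature_table",
    "FEATURE_REGISTRY",
]


@dataclass
class FeatureImages:
    """Stack of per-pixel feature images sharing the frame shape."""

    images: dict[str, np.ndarray]
    feature_names: list[str]

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) > 1:
            raise DimensionError(f"feature images differ in shape: {shapes}")
        missing = [n for n in self.feature_names if n not in self.images]
        if missing:
            raise ValidationError(f"missing feature images: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def as_array(self) -> np.ndarray:
        """(H, W, n_features) array in feature_names order."""
        return np.stack([self.images[n] for n in self.feature_names], axis=-1)


@dataclass
class FeatureTable:
    """Per-pixel training rows assembled from self-labeled pixels."""

    X: np.ndarray  # (n_rows, n_features)
    y: np.ndarray  # (n_rows,) in {CELL, BACKGROUND}
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(*np.unique(self.y, return_counts=True))}


def local_entropy(frame: np.ndarray, radius: int = 5, n_bins: int = 32) -> np.ndarray:
    """Shannon entropy (bits) of the local intensity histogram at each pixel.

    The frame is quantized into ``n_bins`` equal-width bins spanning its own
    [min, max] range; the histogram at each pixel is taken over the disk
    neighborhood of the given radius with reflective border padding.  A
    constant frame has zero entropy everywhere.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if radius < 1:
        raise ParameterError("radius must be >= 1")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if radius > min(frame.shape) // 2:
        raise ParameterError(f"radius {radius} too large for frame {frame.shape}")

    lo, hi = frame.min(), frame.max()
    if hi <= lo:
        return np.zeros_like(frame)
    # bin index in [0, n_bins-1]; top edge maps into the last bin
    idx = np.minimum((frame - lo) / (hi - lo) * n_bins, n_bins - 1).astype(np.intp)

    footprint = disk(radius).astype(np.float64)
    total = footprint.sum()
    H = np.zeros_like(frame)
    for b in range(n_bins):
        counts = ndi.correlate((idx == b).astype(np.float64), footprint, mode="reflect")
        p = counts / total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log2(p), 0.0)
        H += term
    return H


def local_gradient(frame: np.ndarray, smoothing_sigma: float = 1.0) -> np.ndarray:
    """Gradient magnitude of the (optionally Gaussian-smoothed) frame.

    Central differences on the smoothed frame, reflective borders; a linear
    ramp of slope s yields gradient ~ s in the interior.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if smoothing_sigma < 0:
        raise ParameterError("smoothing_sigma must be >= 0")
    if smoothing_sigma > 0:
        frame = ndi.gaussian_filter(frame, smoothing_sigma, mode="reflect")
    gy = ndi.correlate1d(frame, [0.5, 0.0, -0.5], axis=0, mode="reflect")
    gx = ndi.correlate1d(frame, [0.5, 0.0, -0.5], axis=1, mode="reflect")
    return np.hypot(gy, gx)


FEATURE_REGISTRY = {
    "entropy": lambda frame, cfg: local_entropy(
        frame, radius=cfg.get("entropy_radius", 5), n_bins=cfg.get("entropy_bins", 32)
    ),
    "gradient": lambda frame, cfg: local_gradient(
        frame, smoothing_sigma=cfg.get("gradient_sigma", 1.0)
    ),
    "intensity": lambda frame, cfg: np.asarray(frame, dtype=np.float64),
}


def compute_features(frame: np.ndarray, feature_names=("entropy", "gradient"), config: dict | None = None) -> FeatureImages:
    """Evaluate the named registry features on one frame."""
    cfg = config or {}
    unknown = [n for n in feature_names if n not in FEATURE_REGISTRY]
    if unknown:
        raise ParameterError(f"unknown features: {unknown}")
    images = {n: FEATURE_REGISTRY[n](frame, cfg) for n in feature_names}
    return FeatureImages(images=images, feature_names=list(feature_names))


def build_feature_table(features: FeatureImages, labels: LabelMap) -> FeatureTable:
    """One row per self-labeled pixel; UNLABELED pixels are excluded."""
    if features.shape != labels.labels.shape:
        raise DimensionError(
            f"feature shape {features.shape} != label shape {labels.labels.shape}"
        )
    arr = features.as_array()
    rows_mask = (labels.labels == CELL) | (labels.labels == BACKGROUND)
    y = labels.labels[rows_mask]
    if not np.any(y == CELL) or not np.any(y == BACKGROUND):
        raise EmptyClassError("both CELL and BACKGROUND pixels are required")
    X = arr[rows_mask]
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values in training table")
    return FeatureTable(X=X, y=y, feature_names=list(features.feature_names))
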