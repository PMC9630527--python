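"""Gaussian Naïve Bayes pixel classifier trained on self-labeled pixels.

A fresh model is fit for every frame pair, so the classifier continuously
adapts to drifting illumination and changing phenotypes.  Class priors are
the empirical label frequencies (the over-segmented background labeling is
deliberately imbalanced and the prior should say so); likelihoods are
independent Gaussians per feature, evaluated in log space so extreme feature
values saturate the posterior instead of overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import EmptyClassError, ParameterError, ValidationError
from .features import FeatureImages, FeatureTable
from .labeling import CELL, BACKGROUND

__all__ = ["PixelClassifierModel", "fit_naive_bayes", "classify_pixels"]

_CLASSES = (BACKGROUND, CELL)


@dataclass
class PixelClassifierModel:
    """Per-class Gaussian parameters and priors over the feature vector."""

    class_priors: np.ndarray     # (2,) ordered (BACKGROUND, CELL)
    class_means: np.ndarray      # (2, n_features)
    class_variances: np.ndarray  # (2, n_features), floored
    variance_floor: float
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def fit_naive_bayes(table: FeatureTable, variance_floor: float = 1e-6, priors: str = "empirical") -> PixelClassifierModel:
    """Fit per-class Gaussian moments and priors from a feature table.

    Variances use the population (maximum-likelihood) convention and are
    floored at ``variance_floor`` so constant features stay well-defined.
    ``priors`` is "empirical" (default) or "uniform".
    """
    if variance_floor <= 0:
        raise ParameterError("variance_floor must be > 0")
    means, variances, counts = [], [], []
    for c in _CLASSES:
        Xc = table.X[table.y == c]
        if Xc.shape[0] == 0:
            raise EmptyClassError(f"class {c} has no rows")
        means.append(Xc.mean(axis=0))
        variances.append(np.maximum(Xc.var(axis=0), variance_floor))
        counts.append(Xc.shape[0])
    counts = np.asarray(counts, dtype=np.float64)
    if priors == "empirical":
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(2, 0.5)
    else:
        raise ParameterError(f"unknown priors mode {priors!r}")
    return PixelClassifierModel(
        class_priors=pri,
        class_means=np.stack(means),
        class_variances=np.stack(variances),
        variance_floor=variance_floor,
        feature_names=list(table.feature_names),
    )


def _log_joint(model: PixelClassifierModel, X: np.ndarray) -> np.ndarray:
    """log P(class) + log P(X | class) for each row; shape (n, 2)."""
    out = np.empty((X.shape[0], 2))
    for k in range(2):
        mu = model.class_means[k]
        var = model.class_variances[k]
        ll = -0.5 * (np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var).sum(axis=1)
        out[:, k] = np.log(model.class_priors[k]) + ll
    return out


def classify_pixels(model: PixelClassifierModel, features: FeatureImages):
    """Classify every pixel of the frame with the trained model.

    Returns
    -------
    posterior : ndarray
        Per-pixel P(CELL | features) in [0, 1].
    raw_mask : ndarray of bool
        posterior > 0.5 (maximum a posteriori; exact ties go to background).
    """
    if list(features.feature_names) != list(model.feature_names):
        raise ValidationError(
            f"feature names {features.feature_names} do not match model "
            f"{model.feature_names}"
        )
    arr = features.as_array()
    H, W, F = arr.shape
    if F != model.n_features:
        raise ValidationError("feature dimension mismatch")
    lj = _log_joint(model, arr.reshape(-1, F))
    log_post_cell = lj[:, 1] - logsumexp(lj, axis=1)
    posterior = np.exp(log_post_cell).reshape(H, W)
    return posterior, posterior > 0.5
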