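"""Motion-based self-labeling of pixels from the displacement magnitude field.

The highest-displacement pixels are labeled CELL, the lowest BACKGROUND, and
the rest remain UNLABELED — a ternary partition that supplies high-confidence
training data without human annotation.  For low-contrast imagery where the
initial high threshold yields too few or poorly separated cell pixels, the
cell quantile is reduced iteratively until the entropy distributions of the
two labeled sets are well distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import DegenerateLabelingError, ParameterError, TuningFailureError

__all__ = [
    "CELL",
    "BACKGROUND",
    "UNLABELED",
    "LabelMap",
    "ThresholdPolicy",
    "label_from_flow",
    "auto_tune_cell_threshold",
    "entropy_separation",
]

CELL = 1
BACKGROUND = 0
UNLABELED = -1


@dataclass
class LabelMap:
    """Ternary per-pixel self-labels with the magnitude cutoffs that made them."""

    labels: np.ndarray  # values in {CELL, BACKGROUND, UNLABELED}
    high_thresh: float
    low_thresh: float
    tuning_iterations: int = 0

    @property
    def n_cell(self) -> int:
        return int(np.count_nonzero(self.labels == CELL))

    @property
    def n_background(self) -> int:
        return int(np.count_nonzero(self.labels == BACKGROUND))


@dataclass(frozen=True)
class ThresholdPolicy:
    """Knobs of the self-labeling thresholds and the adaptive reduction.

    ``cell_quantile`` seeds CELL labels from the top tail of the magnitude
    distribution (conservative by default: top 2%); ``background_quantile``
    labels everything below the median BACKGROUND, mirroring deliberate
    over-segmentation of motion.  The adaptive loop lowers ``cell_quantile``
    by ``quantile_step`` until at least ``min_cell_pixels`` are labeled and
    the standardized entropy separation between the labeled sets reaches
    ``separation_min``.
    """

    cell_quantile: float = 0.98
    background_quantile: float = 0.50
    min_cell_pixels: int = 500
    separation_min: float = 1.0
    quantile_step: float = 0.02
    max_iterations: int = 20
    cell_erosion_radius: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.background_quantile < self.cell_quantile < 1.0):
            raise ParameterError(
                "need 0 < background_quantile < cell_quantile < 1, got "
                f"({self.background_quantile}, {self.cell_quantile})"
            )
        if self.quantile_step <= 0:
            raise ParameterError("quantile_step must be > 0")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPolicy":
        return cls(**d)


def label_from_flow(magnitude: np.ndarray, policy: ThresholdPolicy | None = None, *, cell_quantile: float | None = None) -> LabelMap:
    """Threshold the magnitude field into CELL / BACKGROUND / UNLABELED.

    CELL pixels have magnitude strictly above the ``cell_quantile`` quantile,
    BACKGROUND pixels at or below the ``background_quantile`` quantile;
    quantiles are taken over all pixels.  A constant magnitude field has no
    separable regimes and raises :class:`DegenerateLabelingError`.

    If ``policy.cell_erosion_radius`` > 0, the CELL set is eroded by a disk
    of that radius (the removed pixels become UNLABELED): a dense flow
    field's support exceeds the true moving support by roughly the
    aggregation window half-width, so restricting seeds to pixels whose
    whole neighborhood is fast-moving keeps them strictly inside cells.
    Every surviving CELL pixel still has magnitude above the threshold.
    """
    if policy is None:
        policy = ThresholdPolicy()
    magnitude = np.asarray(magnitude, dtype=np.float64)
    cq = policy.cell_quantile if cell_quantile is None else cell_quantile
    if not (policy.background_quantile < cq < 1.0):
        raise ParameterError(f"invalid cell quantile {cq}")

    high = float(np.quantile(magnitude, cq))
    low = float(np.quantile(magnitude, policy.background_quantile))
    if high <= low or np.ptp(magnitude) == 0.0:
        raise DegenerateLabelingError(
            "magnitude field has no separable high/low displacement regimes"
        )
    labels = np.full(magnitude.shape, UNLABELED, dtype=np.int8)
    cell_mask = magnitude > high
    if policy.cell_erosion_radius > 0:
        cell_mask = ndi.binary_erosion(
            cell_mask, structure=disk(policy.cell_erosion_radius)
        )
    labels[cell_mask] = CELL
    labels[magnitude <= low] = BACKGROUND
    return LabelMap(labels=labels, high_thresh=high, low_thresh=low)


def entropy_separation(entropy_image: np.ndarray, labels: LabelMap) -> float:
    """Standardized separation of entropy values between the labeled sets.

    A Cohen's-d-like statistic: |mean(E_cell) - mean(E_bg)| / pooled std.
    Returns 0 when either class is empty or the pooled spread vanishes.
    """
    e = np.asarray(entropy_image, dtype=np.float64)
    ec = e[labels.labels == CELL]
    eb = e[labels.labels == BACKGROUND]
    if ec.size == 0 or eb.size == 0:
        return 0.0
    pooled_var = (ec.size * ec.var() + eb.size * eb.var()) / (ec.size + eb.size)
    if pooled_var <= 0:
        return 0.0
    return float(abs(ec.mean() - eb.mean()) / np.sqrt(pooled_var))


def auto_tune_cell_threshold(
    magnitude: np.ndarray, entropy_image: np.ndarray, policy: ThresholdPolicy | None = None
) -> LabelMap:
    """Self-label with adaptive reduction of the cell threshold.

    Starting at ``policy.cell_quantile``, the quantile is reduced by
    ``quantile_step`` per iteration until the CELL set is large enough
    (``min_cell_pixels``) and its entropy distribution is well distinguished
    from the BACKGROUND one (``separation_min`` pooled standard deviations).
    Raises :class:`TuningFailureError` carrying the best map seen if the
    criteria are never met.
    """
    if policy is None:
        policy = ThresholdPolicy()
    best: LabelMap | None = None
    best_score = -np.inf
    cq = policy.cell_quantile
    min_cq = policy.background_quantile + policy.quantile_step
    for it in range(policy.max_iterations):
        try:
            lm = label_from_flow(magnitude, policy, cell_quantile=cq)
        except DegenerateLabelingError:
            lm = None
        if lm is not None:
            sep = entropy_separation(entropy_image, lm)
            lm.tuning_iterations = it + 1
            score = sep if lm.n_cell >= policy.min_cell_pixels else sep - 1e6
            if score > best_score:
                best, best_score = lm, score
            if lm.n_cell >= policy.min_cell_pixels and sep >= policy.separation_min:
                return lm
        cq = cq - policy.quantile_step
        if cq < min_cq:
            break
    raise TuningFailureError(
        "adaptive threshold reduction did not reach the stopping criteria",
        best_labels=best,
        iterations=(best.tuning_iterations if best is not None else policy.max_iterations),
    )
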