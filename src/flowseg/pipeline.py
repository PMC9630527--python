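"""End-to-end per-frame-pair segmentation and pixel-wise evaluation.

For every consecutive pair (t-1, t) the pipeline computes dense optical
flow, self-labels the extreme-displacement pixels, extracts static texture
features on frame t, trains a fresh Naïve Bayes model on the self-labeled
pixels, classifies every pixel, and post-processes the raw mask (hole
filling, motion-derived size filtering).  Each pair is handled
independently — the most recent imagery is always the training data — so the
model tracks drifting backgrounds without manual intervention.  The whole
loop is deterministic and seed-free at inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import PixelClassifierModel, classify_pixels, fit_naive_bayes
from .config import PipelineConfig
from .errors import DimensionError, EmptyClassError, SizeEstimationError, TuningFailureError, ValidationError
from .features import build_feature_table, compute_features
from .flow import farneback_displacement
from .io import ImageStack
from .labeling import auto_tune_cell_threshold
from .postprocess import ComponentRecord, estimate_mean_cell_area, fill_holes, size_filter

logger = logging.getLogger("flowseg")

__all__ = ["SegmentationResult", "EvalResult", "segment_pair", "segment_stack", "f1_score"]

STATUS_OK = "ok"
STATUS_SKIPPED = "skipped_degenerate"
STATUS_TUNING_WARNED = "tuning_warned"


@dataclass
class SegmentationResult:
    """Final mask for frame t of the pair (t-1, t) with provenance."""

    frame_index: int
    mask: np.ndarray
    components: list[ComponentRecord] = field(default_factory=list)
    thresholds_used: tuple[float, float] = (float("nan"), float("nan"))
    tuning_iterations: int = 0
    status: str = STATUS_OK
    model: PixelClassifierModel | None = None


@dataclass
class EvalResult:
    """Pixel-wise confusion counts and the F1 overlap score."""

    tp: int
    fp: int
    fn: int
    f1: float


def segment_pair(
    prev: np.ndarray,
    curr: np.ndarray,
    config: PipelineConfig | None = None,
    *,
    frame_index: int = 1,
    fallback_model: PixelClassifierModel | None = None,
) -> SegmentationResult:
    """Segment frame ``curr`` using motion relative to ``prev``.

    If self-labeling is degenerate (no motion) the previous trained model is
    reused when supplied; otherwise the frame is reported unsegmented with
    status ``skipped_degenerate``.
    """
    if config is None:
        config = PipelineConfig()
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.shape != curr.shape:
        raise DimensionError(f"frame shapes differ: {prev.shape} vs {curr.shape}")

    flow = farneback_displacement(prev, curr, config.flow)
    magnitude = flow.magnitude
    features = compute_features(curr, config.features.names, config.features.options())
    entropy_img = features.images.get("entropy")
    if entropy_img is None:
        entropy_img = compute_features(curr, ("entropy",), config.features.options()).images["entropy"]

    status = STATUS_OK
    labels, exhausted = _tune_labels(magnitude, entropy_img, config.labeling, frame_index)
    if labels is None:
        logger.warning("frame %d: degenerate labeling, no model to fall back on", frame_index)
        return _fallback_result(curr, frame_index, fallback_model, features, config)
    if exhausted:
        status = STATUS_TUNING_WARNED
        logger.warning("frame %d: threshold tuning exhausted; best-effort labels used", frame_index)

    try:
        table = build_feature_table(features, labels)
        model = fit_naive_bayes(
            table, config.classifier.variance_floor, config.classifier.priors
        )
    except (EmptyClassError, ValidationError):
        return _fallback_result(curr, frame_index, fallback_model, features, config)

    _, raw_mask = classify_pixels(model, features)
    mask, components = _postprocess(raw_mask, magnitude, config, frame_index)

    logger.info(
        "frame %d: high=%.4g low=%.4g n_cell=%d n_bg=%d iters=%d kept=%d status=%s",
        frame_index, labels.high_thresh, labels.low_thresh, labels.n_cell,
        labels.n_background, labels.tuning_iterations,
        sum(c.kept for c in components), status,
    )
    return SegmentationResult(
        frame_index=frame_index,
        mask=mask,
        components=components,
        thresholds_used=(labels.high_thresh, labels.low_thresh),
        tuning_iterations=labels.tuning_iterations,
        status=status,
        model=model,
    )


def _tune_labels(magnitude, entropy_img, policy, frame_index):
    """Adaptive labeling with a seed-erosion relaxation ladder.

    When the CELL seeds are eroded by the flow-halo radius, very small cells
    can leave too few seeds at any quantile; in that case the erosion is
    relaxed step by step (same spirit as the threshold reduction itself)
    before falling back to the best labels seen.
    """
    import dataclasses as _dc

    best = None
    radius = policy.cell_erosion_radius
    while True:
        pol = _dc.replace(policy, cell_erosion_radius=radius)
        try:
            return auto_tune_cell_threshold(magnitude, entropy_img, pol), False
        except TuningFailureError as err:
            if err.best_labels is not None:
                best = err.best_labels
            if radius == 0:
                return best, True
            next_radius = radius // 2 if radius > 2 else 0
            logger.info(
                "frame %d: tuning exhausted at seed erosion %d; relaxing to %d",
                frame_index, radius, next_radius,
            )
            radius = next_radius


def _postprocess(raw_mask, magnitude, config, frame_index):
    mask = fill_holes(raw_mask, radius=config.postprocess.fill_radius)
    components: list[ComponentRecord] = []
    if config.postprocess.size_filter_enabled:
        try:
            area = estimate_mean_cell_area(
                magnitude,
                config.labeling,
                radius=config.postprocess.fill_radius,
                halo_radius=config.flow.window_size // 2,
            )
            mask, components = size_filter(mask, area, config.postprocess.min_fraction)
        except SizeEstimationError:
            logger.warning("frame %d: cell size estimation failed; size filter disabled", frame_index)
            _, components = size_filter(mask, 1.0, config.postprocess.min_fraction)
    return mask, components


def _fallback_result(curr, frame_index, fallback_model, features, config):
    if fallback_model is not None:
        _, raw_mask = classify_pixels(fallback_model, features)
        mask = fill_holes(raw_mask, radius=config.postprocess.fill_radius)
        return SegmentationResult(
            frame_index=frame_index, mask=mask, status=STATUS_SKIPPED, model=fallback_model
        )
    return SegmentationResult(
        frame_index=frame_index,
        mask=np.zeros_like(curr, dtype=bool),
        status=STATUS_SKIPPED,
    )


def segment_stack(stack: ImageStack, config: PipelineConfig | None = None) -> list[SegmentationResult]:
    """Segment every consecutive pair of the stack, fresh model per pair."""
    if stack.n_frames < 2:
        raise ValidationError("segmentation needs at least 2 frames")
    if config is None:
        config = PipelineConfig()
    results: list[SegmentationResult] = []
    last_model: PixelClassifierModel | None = None
    for t in range(1, stack.n_frames):
        res = segment_pair(
            stack[t - 1], stack[t], config, frame_index=t, fallback_model=last_model
        )
        if res.model is not None and res.status != STATUS_SKIPPED:
            last_model = res.model
        results.append(res)
    return results


def f1_score(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Pixel-wise F1 = TP / (TP + (FP + FN)/2) against a ground-truth mask.

    Two empty masks agree perfectly (F1 = 1); an empty prediction against a
    nonempty truth (or vice versa) scores 0.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise DimensionError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    if tp == 0 and fp == 0 and fn == 0:
        f1 = 1.0
    else:
        f1 = tp / (tp + 0.5 * (fp + fn))
    return EvalResult(tp=tp, fp=fp, fn=fn, f1=float(f1))
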