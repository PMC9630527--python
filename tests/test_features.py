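import numpy as np
import pytest

from flowseg import build_feature_table, compute_features, local_entropy, local_gradient
from flowseg.errors import DimensionError, EmptyClassError, ParameterError
from flowseg.labeling import BACKGROUND, CELL, UNLABELED, LabelMap


def _bruteforce_entropy(frame, radius, n_bins):
    """Per-pixel scalar-loop oracle: histogram entropy over the reflected
    disk neighborhood."""
    lo, hi = frame.min(), frame.max()
    idx = np.minimum((frame - lo) / (hi - lo) * n_bins, n_bins - 1).astype(int)
    padded = np.pad(idx, radius, mode="symmetric")  # edge-repeating reflection
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    out = np.zeros(frame.shape)
    for r in range(frame.shape[0]):
        for c in range(frame.shape[1]):
            vals = [padded[r + radius + dy, c + radius + dx] for dy, dx in offs]
            counts = np.bincount(vals, minlength=n_bins).astype(float)
            p = counts / counts.sum()
            p = p[p > 0]
            out[r, c] = -(p * np.log2(p)).sum()
    return out


def test_constant_frame_has_zero_entropy():
    np.testing.assert_array_equal(local_entropy(np.full((20, 20), 0.7)), 0.0)


def test_uniform_noise_entropy_approaches_log2_bins():
    rng = np.random.default_rng(0)
    frame = rng.random((64, 64))
    ent = local_entropy(frame, radius=8, n_bins=8)
    interior = ent[10:-10, 10:-10]
    assert np.abs(interior - 3.0).max() < 0.55  # log2(8)=3, finite-sample
    assert np.abs(interior.mean() - 3.0) < 0.2


def test_checkerboard_entropy_matches_bruteforce_loop():
    frame = np.indices((16, 16)).sum(axis=0) % 2 * 0.8 + 0.1
    got = local_entropy(frame, radius=3, n_bins=4)
    want = _bruteforce_entropy(frame, radius=3, n_bins=4)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_random_frame_entropy_matches_bruteforce_loop():
    rng = np.random.default_rng(9)
    frame = rng.random((18, 21))
    got = local_entropy(frame, radius=2, n_bins=8)
    want = _bruteforce_entropy(frame, radius=2, n_bins=8)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_entropy_invariant_under_bin_preserving_affine_map():
    rng = np.random.default_rng(4)
    frame = rng.random((30, 30))
    a = local_entropy(frame, radius=3, n_bins=16)
    b = local_entropy(0.25 * frame + 0.3, radius=3, n_bins=16)
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_entropy_parameter_validation():
    with pytest.raises(ParameterError):
        local_entropy(np.zeros((10, 10)), radius=0)
    with pytest.raises(ParameterError):
        local_entropy(np.zeros((10, 10)), radius=8)  # larger than half frame
    with pytest.raises(ParameterError):
        local_entropy(np.zeros((10, 10)), n_bins=1)


def test_gradient_of_constant_is_zero():
    np.testing.assert_array_equal(local_gradient(np.full((15, 15), 0.4)), 0.0)


def test_gradient_of_ramp_recovers_slope():
    s = 0.013
    frame = np.outer(np.ones(40), np.arange(40)) * s
    grad = local_gradient(frame, smoothing_sigma=0.0)
    interior = grad[5:-5, 5:-5]
    assert np.abs(interior - s).max() < 0.05 * s


def test_gradient_matches_bruteforce_central_difference():
    rng = np.random.default_rng(12)
    frame = rng.random((20, 20))
    got = local_gradient(frame, smoothing_sigma=0.0)
    for r in range(2, 18):
        for c in range(2, 18):
            gy = (frame[r + 1, c] - frame[r - 1, c]) / 2.0
            gx = (frame[r, c + 1] - frame[r, c - 1]) / 2.0
            assert got[r, c] == pytest.approx(np.hypot(gy, gx), abs=1e-12)


def test_gradient_translation_equivariance():
    rng = np.random.default_rng(5)
    frame = rng.random((40, 40))
    g = local_gradient(frame, smoothing_sigma=1.0)
    g_shift = local_gradient(np.roll(frame, (3, 2), axis=(0, 1)), smoothing_sigma=1.0)
    np.testing.assert_allclose(np.roll(g, (3, 2), axis=(0, 1))[8:-8, 8:-8], g_shift[8:-8, 8:-8], atol=1e-10)


def test_feature_table_counts_and_indexing_oracle():
    rng = np.random.default_rng(1)
    frame = rng.random((25, 25))
    feats = compute_features(frame)
    labels = np.full((25, 25), UNLABELED, dtype=np.int8)
    bgs = [(i, 24 - i) for i in range(20)]
    cells = [(3, 4), (10, 11), (20, 2), (7, 7), (1, 1), (5, 18), (14, 3), (22, 22), (9, 0), (0, 9)]
    assert not set(cells) & set(bgs)
    for r, c in cells:
        labels[r, c] = CELL
    for r, c in bgs:
        labels[r, c] = BACKGROUND
    lm = LabelMap(labels=labels, high_thresh=1.0, low_thresh=0.0)
    table = build_feature_table(feats, lm)
    assert table.X.shape == (30, 2)
    assert table.class_counts == {CELL: 10, BACKGROUND: 20}
    # indexing oracle: each row equals the feature images at its coordinates
    arr = feats.as_array()
    rows = [(r, c) for r, c in zip(*np.nonzero(labels != UNLABELED))]
    got = {tuple(x) for x in table.X}
    want = {tuple(arr[r, c]) for r, c in rows}
    assert got == want


def test_feature_table_requires_both_classes():
    frame = np.random.default_rng(0).random((10, 10))
    feats = compute_features(frame)
    lm = LabelMap(labels=np.full((10, 10), UNLABELED, dtype=np.int8), high_thresh=1, low_thresh=0)
    with pytest.raises(EmptyClassError):
        build_feature_table(feats, lm)


def test_feature_shape_mismatch_rejected():
    feats = compute_features(np.zeros((10, 10)))
    lm = LabelMap(labels=np.zeros((11, 11), dtype=np.int8), high_thresh=1, low_thresh=0)
    with pytest.raises(DimensionError):
        build_feature_table(feats, lm)


def test_feature_registry_extension():
    frame = np.random.default_rng(0).random((12, 12))
    feats = compute_features(frame, ("entropy", "gradient", "intensity"))
    assert feats.n_features == 3
    np.testing.assert_array_equal(feats.images["intensity"], frame)
    with pytest.raises(ParameterError):
        compute_features(frame, ("entropy", "nope"))
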