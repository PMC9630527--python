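import numpy as np
import pytest

from flowseg import classify_pixels, compute_features, fit_naive_bayes
from flowseg.classifier import PixelClassifierModel
from flowseg.errors import EmptyClassError, ValidationError
from flowseg.features import FeatureImages, FeatureTable
from flowseg.labeling import BACKGROUND, CELL


def _table(Xc, Xb, names=("entropy", "gradient")):
    X = np.vstack([Xc, Xb])
    y = np.array([CELL] * len(Xc) + [BACKGROUND] * len(Xb))
    return FeatureTable(X=X.astype(float), y=y, feature_names=list(names))


def test_fitted_moments_match_hand_computation():
    table = _table([(0, 0), (2, 2)], [(10, 10), (12, 12)])
    model = fit_naive_bayes(table)
    np.testing.assert_allclose(model.class_priors, [0.5, 0.5])
    np.testing.assert_allclose(model.class_means[1], [1.0, 1.0])   # CELL
    np.testing.assert_allclose(model.class_means[0], [11.0, 11.0])  # BACKGROUND
    np.testing.assert_allclose(model.class_variances, 1.0)  # population convention


def test_constant_feature_variance_is_floored():
    table = _table([(1.0, 5.0), (1.0, 7.0)], [(2.0, 0.0), (2.0, 1.0)])
    model = fit_naive_bayes(table, variance_floor=1e-6)
    assert model.class_variances[1][0] == 1e-6
    assert model.class_variances[0][0] == 1e-6


def test_parameter_recovery_on_simulated_gaussians():
    rng = np.random.default_rng(8)
    n = 4000
    Xc = rng.normal([2.0, -1.0], [0.5, 1.5], size=(n, 2))
    Xb = rng.normal([-3.0, 4.0], [2.0, 0.3], size=(n, 2))
    model = fit_naive_bayes(_table(Xc, Xb))
    for k, (mu, sd) in [(1, ([2.0, -1.0], [0.5, 1.5])), (0, ([-3.0, 4.0], [2.0, 0.3]))]:
        se = np.asarray(sd) / np.sqrt(n)
        assert (np.abs(model.class_means[k] - mu) < 3 * se).all()


def test_single_class_table_rejected():
    X = np.zeros((5, 2))
    y = np.full(5, CELL)
    with pytest.raises(EmptyClassError):
        fit_naive_bayes(FeatureTable(X=X, y=y, feature_names=["entropy", "gradient"]))


def _feature_images(arr, names=("entropy", "gradient")):
    return FeatureImages(
        images={n: arr[..., i] for i, n in enumerate(names)}, feature_names=list(names)
    )


def test_decision_boundary_matches_analytic_midpoint():
    """1-D equal-variance, equal-prior Gaussians decide at (mu1+mu2)/2."""
    model = PixelClassifierModel(
        class_priors=np.array([0.5, 0.5]),
        class_means=np.array([[4.0], [1.0]]),  # BACKGROUND at 4, CELL at 1
        class_variances=np.array([[1.0], [1.0]]),
        variance_floor=1e-6,
        feature_names=["entropy"],
    )
    mid = 2.5
    xs = np.array([[mid - 1e-7, mid + 1e-7, mid]])
    feats = _feature_images(xs[..., None], names=("entropy",))
    post, mask = classify_pixels(model, feats)
    assert post[0, 0] > 0.5 and mask[0, 0]          # below midpoint -> CELL side
    assert post[0, 1] < 0.5 and not mask[0, 1]
    assert abs(post[0, 2] - 0.5) < 1e-6             # boundary itself
    assert not mask[0, 2]                            # tie -> BACKGROUND


def test_equal_likelihoods_decided_by_prior():
    model = PixelClassifierModel(
        class_priors=np.array([0.7, 0.3]),
        class_means=np.array([[0.0], [0.0]]),
        class_variances=np.array([[1.0], [1.0]]),
        variance_floor=1e-6,
        feature_names=["entropy"],
    )
    feats = _feature_images(np.zeros((1, 1, 1)), names=("entropy",))
    post, mask = classify_pixels(model, feats)
    assert post[0, 0] == pytest.approx(0.3)
    assert not mask[0, 0]


def test_log_space_never_produces_nan_for_extreme_features():
    model = PixelClassifierModel(
        class_priors=np.array([0.5, 0.5]),
        class_means=np.array([[0.0], [1.0]]),
        class_variances=np.array([[1.0], [1.0]]),
        variance_floor=1e-6,
        feature_names=["entropy"],
    )
    xs = np.array([[[1e6], [-1e6], [0.5]]], dtype=float)
    post, _ = classify_pixels(model, _feature_images(xs, names=("entropy",)))
    assert np.isfinite(post).all()
    assert post[0, 0] == 1.0  # saturates toward the nearer class
    assert post[0, 1] == 0.0


def test_posteriors_are_probabilities(default_movie, pipeline_config):
    from flowseg.flow import farneback_displacement
    from flowseg.labeling import auto_tune_cell_threshold
    from flowseg import build_feature_table

    mv = default_movie
    mag = farneback_displacement(mv.stack[0], mv.stack[1]).magnitude
    feats = compute_features(mv.stack[1])
    lm = auto_tune_cell_threshold(mag, feats.images["entropy"], pipeline_config.labeling)
    model = fit_naive_bayes(build_feature_table(feats, lm))
    post, _ = classify_pixels(model, feats)
    assert (post >= 0).all() and (post <= 1).all()


def test_wide_margin_table_resubstitutes_perfectly():
    rng = np.random.default_rng(3)
    Xc = rng.normal([10, 10], 0.1, size=(200, 2))
    Xb = rng.normal([-10, -10], 0.1, size=(300, 2))
    table = _table(Xc, Xb)
    model = fit_naive_bayes(table)
    arr = table.X.reshape(-1, 1, 2)
    feats = _feature_images(arr)
    _, mask = classify_pixels(model, feats)
    pred = np.where(mask.ravel(), CELL, BACKGROUND)
    assert (pred == table.y).all()


def test_reference_implementation_equivalence():
    """Posteriors match sklearn's GaussianNB on random tables to 1e-6."""
    from sklearn.naive_bayes import GaussianNB

    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(20, 200)
        f = rng.integers(1, 4)
        X = rng.normal(size=(n, f)) * rng.uniform(0.5, 3, size=f) + rng.normal(size=f)
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            continue
        names = [f"f{i}" for i in range(f)]
        table = FeatureTable(X=X, y=y, feature_names=names)
        model = fit_naive_bayes(table, variance_floor=1e-12)
        ref = GaussianNB(var_smoothing=0.0).fit(X, y)
        post_ref = ref.predict_proba(X)[:, list(ref.classes_).index(CELL)]
        feats = _feature_images(X.reshape(-1, 1, f), names=tuple(names))
        post, _ = classify_pixels(model, feats)
        assert np.abs(post.ravel() - post_ref).max() < 1e-6


def test_feature_name_mismatch_rejected():
    table = _table([(0, 0)], [(1, 1)])
    model = fit_naive_bayes(table)
    feats = _feature_images(np.zeros((2, 2, 2)), names=("a", "b"))
    with pytest.raises(ValidationError):
        classify_pixels(model, feats)
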