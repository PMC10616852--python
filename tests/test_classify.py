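import numpy as np
import pytest

from spectramir.classify import (ANCHOR_BLOCK, ClassifyConfig, augment,
                                 fit_feature_model, pr_curve, predict,
                                 predict_proba, prepare_crops, preprocess_crop,
                                 symmetrize, train_classifier)


def blob_crop(anchor_value=4.0, background=0.0, sigma=1.15):
    """A clean top-blob crop: Gaussian centred on the anchor block."""
    rr, cc = np.mgrid[0:24, 0:10].astype(float)
    g = np.exp(-((rr - 1.5) ** 2 + (cc - 4.5) ** 2) / (2 * sigma ** 2))
    crop = background + g * anchor_value / g[ANCHOR_BLOCK].mean()
    return crop


class TestPreprocessCrop:
    def test_uniform_crop_rejected_as_flat(self):
        out = preprocess_crop(np.full((24, 10), 3.0))
        assert out.rejected and out.reason == "flat crop"

    def test_anchor_normalization_gives_k_and_unit_mean(self):
        crop = np.zeros((24, 10))
        crop[1:3, 4:6] = 4.0
        out = preprocess_crop(crop)
        assert not out.rejected
        assert out.k == pytest.approx(4.0)
        # reconstruct the normalized full crop: anchor mean must be exactly 1
        normalized = crop / out.k
        assert normalized[ANCHOR_BLOCK].mean() == pytest.approx(1.0, abs=1e-9)

    def test_far_negative_pixel_zeroed_crop_retained(self):
        crop = blob_crop(anchor_value=5.0)
        crop[20, 1] = -0.5
        out = preprocess_crop(crop)
        assert not out.rejected
        # the offending pixel maps to half-crop col 8 mirrored into col index 3
        half = out.half.reshape(24, 5)
        assert np.all(half >= 0)

    def test_negative_anchor_after_edge_median_rejected(self):
        crop = np.full((24, 10), 2.0)   # edge median 2.0
        crop[1:3, 4:6] = 1.0            # anchor below the edge level
        out = preprocess_crop(crop)
        assert out.rejected and out.reason == "negative anchor"

    def test_scale_invariance(self):
        crop = blob_crop(anchor_value=3.0, background=0.1)
        a = preprocess_crop(crop)
        b = preprocess_crop(7.0 * crop)
        assert b.k == pytest.approx(7.0 * a.k)
        np.testing.assert_allclose(a.half, b.half, atol=1e-12)

    def test_batch_path_matches_single_crop_path(self):
        rng = np.random.default_rng(0)
        crops = np.stack([blob_crop(anchor_value=a) + rng.uniform(0, 0.2, (24, 10))
                          for a in (2.0, 5.0, 9.0)])
        halves, k, kept = prepare_crops(crops)
        assert kept.all()
        for i in range(3):
            single = preprocess_crop(crops[i])
            np.testing.assert_allclose(halves[i], single.half, atol=1e-12)
            assert k[i] == pytest.approx(single.k)


class TestSymmetrize:
    def test_output_has_120_values(self):
        rng = np.random.default_rng(1)
        out = symmetrize(rng.uniform(size=(24, 10)))
        assert out.shape == (24, 5)
        assert out.size == 120

    def test_symmetric_crop_doubles_right_half(self):
        rng = np.random.default_rng(2)
        right = rng.uniform(size=(24, 5))
        crop = np.hstack([right[:, ::-1], right])
        np.testing.assert_allclose(symmetrize(crop), 2.0 * right)

    def test_matches_brute_force_flip_add(self):
        rng = np.random.default_rng(3)
        crop = rng.uniform(size=(24, 10))
        out = symmetrize(crop)
        for r in range(24):
            for j in range(5, 10):
                expected = crop[r, j] + crop[r, 9 - j]
                assert out[r, j - 5] == pytest.approx(expected)

    def test_single_corner_pixel(self):
        crop = np.zeros((24, 10))
        crop[0, 0] = 1.0
        out = symmetrize(crop)
        expected = np.zeros((24, 5))
        expected[0, 4] = 1.0   # col 0 mirrors onto col 9 -> half index 4
        np.testing.assert_array_equal(out, expected)

    def test_mirror_invariance(self):
        rng = np.random.default_rng(4)
        crop = rng.uniform(size=(24, 10))
        np.testing.assert_allclose(symmetrize(crop), symmetrize(crop[:, ::-1]))


class TestAugment:
    def test_triples_the_set_by_default(self):
        rng = np.random.default_rng(5)
        crops = rng.uniform(1, 2, size=(100, 24, 10))
        labels = np.array(["a", "b"] * 50)
        out_c, out_l = augment(crops, labels, seed=0)
        assert out_c.shape[0] == 300
        assert len(out_l) == 300

    def test_label_multiset_scaled_exactly(self):
        import collections

        rng = np.random.default_rng(6)
        crops = rng.uniform(size=(30, 24, 10))
        labels = np.array(["x"] * 10 + ["y"] * 15 + ["noise"] * 5)
        _, out_l = augment(crops, labels, seed=1)
        counts = collections.Counter(out_l)
        assert counts == {"x": 30, "y": 45, "noise": 15}

    def test_zero_noise_copies_identical(self):
        rng = np.random.default_rng(7)
        crops = rng.uniform(size=(4, 24, 10))
        labels = np.array(["a"] * 4)
        out_c, _ = augment(crops, labels, noise_sd=0.0, seed=2)
        np.testing.assert_array_equal(out_c[4:8], crops)
        np.testing.assert_array_equal(out_c[8:12], crops)


class TestFeatureModel:
    def make_halves(self, n=200, seed=8):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(5, 120))
        w = rng.normal(size=(n, 5))
        halves = w @ base + 0.1 * rng.normal(size=(n, 120))
        k = rng.uniform(1, 5, size=n)
        return halves, k

    def test_feature_dimension_is_components_plus_k(self):
        halves, k = self.make_halves()
        fm = fit_feature_model(halves, k, n_components=20)
        feats = fm.transform(halves, k)
        assert feats.shape == (200, 21)

    def test_nested_subspace_reconstruction_error(self):
        halves, k = self.make_halves()
        errs = {}
        for n_comp in (10, 20):
            fm = fit_feature_model(halves, k, n_components=n_comp)
            coeffs = fm.pca.transform(halves)
            recon = fm.pca.inverse_transform(coeffs)
            errs[n_comp] = np.linalg.norm(halves - recon)
        assert errs[20] <= errs[10]

    def test_training_features_standardized(self):
        halves, k = self.make_halves()
        fm = fit_feature_model(halves, k, n_components=20)
        feats = fm.transform(halves, k)
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(feats.var(axis=0), 1.0, atol=1e-6)

    def test_too_few_samples_raise(self):
        halves, k = self.make_halves(n=10)
        with pytest.raises(ValueError):
            fit_feature_model(halves, k, n_components=20)


def separable_features(n_per_class=60, seed=9):
    """Four well-separated Gaussian clusters in 21-d feature space."""
    rng = np.random.default_rng(seed)
    classes = ["c1", "c2", "c3", "noise"]
    centers = 8.0 * np.eye(4)
    X, y = [], []
    for i, cls in enumerate(classes):
        pts = rng.normal(size=(n_per_class, 21)) * 0.3
        pts[:, :4] += centers[i]
        X.append(pts)
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestClassifier:
    def test_separable_clusters_validated_perfectly(self):
        X, y = separable_features()
        model = train_classifier(X, y, feature_model=None, seed=0)
        assert model.validation["accuracy"] == 1.0
        assert model.validation["n_val"] == round(0.1 * len(y))

    def test_training_is_deterministic(self):
        X, y = separable_features()
        m1 = train_classifier(X, y, feature_model=None, seed=3)
        m2 = train_classifier(X, y, feature_model=None, seed=3)
        np.testing.assert_array_equal(m1.n_support, m2.n_support)

    def test_predictions_recover_training_labels(self):
        X, y = separable_features()
        model = train_classifier(X, y, feature_model=None, seed=1)
        np.testing.assert_array_equal(predict(model, X), y)

    def test_probability_vector_contract(self):
        X, y = separable_features()
        model = train_classifier(X, y, feature_model=None, seed=2)
        proba = predict_proba(model, X[:50])
        assert proba.shape == (50, 4)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba.to_numpy() >= 0).all() and (proba.to_numpy() <= 1).all()

    def test_predict_is_argmax_of_proba(self):
        X, y = separable_features()
        model = train_classifier(X, y, feature_model=None, seed=4)
        proba = predict_proba(model, X)
        np.testing.assert_array_equal(
            predict(model, X),
            proba.columns.to_numpy()[np.argmax(proba.to_numpy(), axis=1)])

    def test_missing_class_raises(self):
        X, y = separable_features()
        with pytest.raises(ValueError):
            train_classifier(X[:1], y[:1], feature_model=None, seed=0)


def test_empirical_psf_is_pixelwise_median():
    from spectramir.classify import empirical_psf

    rng = np.random.default_rng(11)
    crops = blob_crop(5.0)[None] + rng.normal(scale=0.2, size=(101, 24, 10))
    psf = empirical_psf(crops)
    np.testing.assert_allclose(psf, np.median(crops, axis=0), atol=1e-12)
    assert psf.shape == (24, 10)


class TestPrCurve:
    def test_perfect_scores_give_unit_auc(self):
        y = np.array([1, 1, 0, 0, 1])
        scores = y.astype(float)
        curve, auc = pr_curve(scores, y)
        assert auc == pytest.approx(1.0)
        low = curve[curve["threshold"] == 0.0]
        assert low["recall"].iloc[0] == 1.0

    def test_constant_scores_precision_equals_prevalence(self):
        y = np.array([1, 0] * 20)
        scores = np.full(40, 0.5)
        curve, _ = pr_curve(scores, y)
        attained = curve.dropna(subset=["precision"])
        attained = attained[attained["recall"] > 0]
        np.testing.assert_allclose(attained["precision"], 0.5)

    def test_matches_brute_force_confusion_sweep(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(size=200)
        y = rng.uniform(size=200) < scores  # correlated labels
        thresholds = np.linspace(0, 1, 21)
        curve, _ = pr_curve(scores, y, thresholds)
        for t, row in zip(thresholds, curve.itertuples(index=False)):
            tp = fp = fn = 0
            for s, yi in zip(scores, y):
                pred = s >= t
                tp += pred and yi
                fp += pred and not yi
                fn += (not pred) and yi
            assert row.recall == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert row.precision == pytest.approx(tp / (tp + fp))

    def test_no_positives_raise(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.5, 0.2]), np.array([0, 0]))
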