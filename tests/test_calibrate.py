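import numpy as np
import pandas as pd
import pytest

from spectramir.calibrate import (ConfusionMatrix, class_metrics,
                                  composition_to_plane, confusion,
                                  count_vector, estimate_uncertainty,
                                  normalized_confusion, plane_to_composition,
                                  ratio_estimate, unconfuse)

CLASSES4 = ["a", "b", "c", "noise"]


def realistic_cm(n_per_class=1000, recall=(0.85, 0.9, 0.88),
                 noise_leak=(0.01, 0.012, 0.008)) -> ConfusionMatrix:
    """A plausible 4-class confusion matrix: errors mostly class<->noise."""
    c = np.zeros((4, 4))
    for i in range(3):
        c[i, i] = round(n_per_class * recall[i])
        c[i, 3] = n_per_class - c[i, i]
    c[3, :3] = [round(2 * n_per_class * l) for l in noise_leak]
    c[3, 3] = 2 * n_per_class - c[3, :3].sum()
    return ConfusionMatrix(c, CLASSES4)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array(["a", "b", "b", "noise", "c"])
        cm = confusion(y, y, CLASSES4)
        np.testing.assert_array_equal(cm.counts,
                                      np.diag([1, 2, 1, 1]))

    def test_hand_counted_two_class_example(self):
        cm = confusion(["a", "a", "b"], ["a", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        t = rng.choice(CLASSES4, size=57)
        p = rng.choice(CLASSES4, size=57)
        assert confusion(t, p, CLASSES4).total == 57

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["a"], ["zzz"], CLASSES4)


class TestClassMetrics:
    def test_identity_matrix_perfect_metrics(self):
        cm = ConfusionMatrix(np.diag([5, 6, 7, 8]), CLASSES4)
        m = class_metrics(cm)
        assert (m.recall == 1.0).all()
        assert (m.precision == 1.0).all()

    def test_two_class_arithmetic(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["a", "b"])
        m = class_metrics(cm)
        assert m.recall["a"] == pytest.approx(0.8)
        assert m.precision["a"] == pytest.approx(8 / 9)

    def test_empty_true_class_flagged_not_zero(self):
        cm = ConfusionMatrix(np.array([[0, 0], [3, 4]]), ["a", "b"])
        m = class_metrics(cm)
        assert np.isnan(m.recall["a"])
        assert m.recall["b"] == pytest.approx(4 / 7)


class TestUnconfuse:
    def test_diagonal_confusion_is_identity(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30, 40]), CLASSES4)
        h = np.array([3.0, 5.0, 7.0, 11.0])
        np.testing.assert_allclose(unconfuse(cm, h), h)

    def test_exact_identity_on_self_consistent_counts(self):
        """Correcting the labeled set's own predicted counts recovers its
        true counts to machine precision, for any confusion matrix."""
        rng = np.random.default_rng(1)
        counts = rng.integers(5, 200, size=(4, 4)).astype(float)
        cm = ConfusionMatrix(counts, CLASSES4)
        h_pred = counts.sum(axis=0)          # predicted counts (column sums)
        h_true = counts.sum(axis=1)          # true counts (row sums)
        np.testing.assert_allclose(unconfuse(cm, h_pred), h_true, rtol=1e-12)

    def test_total_count_conserved(self):
        cm = realistic_cm()
        h = np.array([900.0, 1100.0, 950.0, 2100.0])
        h_prime = unconfuse(cm, h)
        assert h_prime.sum() == pytest.approx(h.sum(), rel=1e-6)

    def test_singular_matrix_rejected(self):
        counts = np.diag([10.0, 10.0, 10.0, 10.0])
        counts[0, :] = 0  # empty true class
        with pytest.raises(ValueError):
            unconfuse(ConfusionMatrix(counts, CLASSES4), np.ones(4))

    def test_paper_convention_available(self):
        cm = realistic_cm()
        chat = normalized_confusion(cm, convention="paper")
        np.testing.assert_allclose(chat.sum(axis=0), 1.0)
        chat_g = normalized_confusion(cm, convention="generative")
        np.testing.assert_allclose(chat_g.sum(axis=0), 1.0)
        assert not np.allclose(chat, chat_g)


class TestRatioEstimate:
    def test_equal_counts_give_uniform_composition(self):
        h = np.array([5.0, 5.0, 5.0, 20.0])
        est = ratio_estimate(h, h, CLASSES4)
        np.testing.assert_allclose(est.composition, 1 / 3)

    def test_capture_efficiencies_cancel_exactly(self):
        """Shared per-class efficiencies drop out: 2:5:3 is recovered."""
        eff = np.array([0.7, 1.3, 0.4])
        h_ref = np.append(eff * 100.0, 500.0)
        h_mix = np.append(eff * 100.0 * np.array([2.0, 5.0, 3.0]), 700.0)
        est = ratio_estimate(h_mix, h_ref, CLASSES4)
        np.testing.assert_allclose(est.composition, [0.2, 0.5, 0.3],
                                   rtol=1e-12)

    def test_scale_invariance(self):
        h_ref = np.array([10.0, 20.0, 30.0, 40.0])
        h_mix = np.array([5.0, 50.0, 15.0, 60.0])
        a = ratio_estimate(h_mix, h_ref, CLASSES4)
        b = ratio_estimate(3.5 * h_mix, h_ref, CLASSES4)
        c = ratio_estimate(h_mix, 0.2 * h_ref, CLASSES4)
        np.testing.assert_allclose(a.composition, b.composition)
        np.testing.assert_allclose(a.composition, c.composition)

    def test_zero_reference_class_rejected(self):
        h_ref = np.array([0.0, 10.0, 10.0, 5.0])
        with pytest.raises(ValueError, match="unobserved"):
            ratio_estimate(np.ones(4), h_ref, CLASSES4)


class TestSimplexGeometry:
    def test_plane_roundtrip(self):
        rng = np.random.default_rng(2)
        comp = rng.dirichlet(np.ones(3), size=50)
        xy = composition_to_plane(comp)
        np.testing.assert_allclose(plane_to_composition(xy), comp, atol=1e-12)

    def test_centroid_maps_to_origin(self):
        np.testing.assert_allclose(composition_to_plane(np.full(3, 1 / 3)),
                                   0.0, atol=1e-12)


class TestEstimateUncertainty:
    def test_reps_recorded_and_mean_matches_point_estimate(self):
        cm = realistic_cm()
        h_ref = np.array([850.0, 900.0, 880.0, 2000.0])
        h_mix = np.array([400.0, 1900.0, 800.0, 2100.0])
        est = estimate_uncertainty(cm, h_ref, h_mix, n_reps=4000, seed=3)
        assert est.n_reps == 4000
        point = ratio_estimate(unconfuse(cm, h_mix), unconfuse(cm, h_ref),
                               CLASSES4)
        # the resampling is centred: ensemble mean stays well inside the
        # reported interval around the point estimate
        assert np.all(np.abs(est.composition - point.composition)
                      <= 0.5 * est.half_widths)

    def test_default_reps_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(estimate_uncertainty)
        assert sig.parameters["n_reps"].default == 10_000

    def test_half_widths_shrink_with_counting_statistics(self):
        """With no count noise and ever larger labeled sets, the intervals
        must contract toward zero."""
        h_ref = np.array([850.0, 900.0, 880.0, 2000.0])
        h_mix = np.array([400.0, 1900.0, 800.0, 2100.0])
        widths = []
        for scale in (1.0, 100.0):
            cm = ConfusionMatrix(realistic_cm().counts * scale, CLASSES4)
            est = estimate_uncertainty(cm, h_ref, h_mix, n_reps=2000,
                                       count_cv=0.0, seed=4)
            widths.append(est.half_widths.max())
        assert widths[1] < 0.2 * widths[0]

    def test_deterministic_per_seed(self):
        cm = realistic_cm()
        h = np.array([500.0, 600.0, 550.0, 1500.0])
        a = estimate_uncertainty(cm, h, h, n_reps=500, seed=7)
        b = estimate_uncertainty(cm, h, h, n_reps=500, seed=7)
        np.testing.assert_array_equal(a.composition, b.composition)
        np.testing.assert_array_equal(a.half_widths, b.half_widths)

    def test_interval_coverage_on_regenerated_truth(self):
        """95% intervals cover the known truth in >= 90% of trials."""
        rng = np.random.default_rng(8)
        true_comp = np.array([0.2, 0.5, 0.3])
        recall = np.array([0.85, 0.9, 0.88, 0.96])
        n_label = np.array([900, 950, 920, 2500])
        leak = np.array([0.01, 0.012, 0.008])
        chat_rows = np.zeros((4, 4))
        for i in range(3):
            chat_rows[i, i] = recall[i]
            chat_rows[i, 3] = 1 - recall[i]
        chat_rows[3, :3] = leak
        chat_rows[3, 3] = 1 - leak.sum()
        hits = np.zeros(3)
        n_trials = 120
        for _ in range(n_trials):
            counts = np.stack([rng.multinomial(n, p)
                               for n, p in zip(n_label, chat_rows)]).astype(float)
            cm = ConfusionMatrix(counts, CLASSES4)
            true_ref = np.array([2000.0, 2000.0, 2000.0, 6000.0])
            true_mix = np.append(2000.0 * 3 * true_comp, 6000.0)
            h_ref = chat_rows.T @ true_ref
            h_mix = chat_rows.T @ true_mix
            h_ref = h_ref * (1 + 0.03 * rng.standard_normal(4))
            h_mix = h_mix * (1 + 0.03 * rng.standard_normal(4))
            est = estimate_uncertainty(cm, h_ref, h_mix, n_reps=400,
                                       count_cv=0.05,
                                       seed=int(rng.integers(2 ** 31)))
            hits += (np.abs(est.composition - true_comp)
                     <= est.half_widths).astype(float)
        assert np.all(hits / n_trials >= 0.9)


def test_count_vector_orders_by_classes():
    labels = np.array(["b", "a", "b", "noise", "b"])
    np.testing.assert_array_equal(count_vector(labels, CLASSES4),
                                  [1, 3, 0, 1])
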