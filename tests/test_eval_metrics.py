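import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periopano import eval_metrics as ev
from periopano.annotations_io import AnnotationScene, PolygonContour


class TestConfusionFromMasks:
    def test_perfect_agreement(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:5] = True
        c = ev.confusion_from_masks(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (50, 0, 0, 50)

    def test_total_disagreement(self):
        pred = np.ones((10, 10), dtype=bool)
        truth = np.zeros((10, 10), dtype=bool)
        c = ev.confusion_from_masks(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 100, 0, 0)

    def test_matches_per_pixel_loop_oracle(self, rng):
        pred = rng.random((4, 4)) > 0.5
        truth = rng.random((4, 4)) > 0.5
        c = ev.confusion_from_masks(pred, truth)
        tp = fp = fn = tn = 0
        for i in range(4):
            for j in range(4):
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_from_masks(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetricsFromConfusion:
    def test_direct_arithmetic_example(self):
        m = ev.metrics_from_confusion(ev.ConfusionCounts(40, 10, 10, 40))
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)
        assert m.dice == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.8)
        assert m.jaccard == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_prediction_all_ones(self):
        m = ev.metrics_from_confusion(ev.ConfusionCounts(50, 0, 0, 50))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_undefined_metric_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = ev.metrics_from_confusion(ev.ConfusionCounts(0, 0, 10, 10))
        assert np.isnan(m.precision)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.metrics_from_confusion(ev.ConfusionCounts(0, 0, 0, 0))

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
        fn=st.integers(0, 10_000), tn=st.integers(0, 10_000),
    )
    def test_metric_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            m = ev.metrics_from_confusion(ev.ConfusionCounts(tp, fp, fn, tn))
        if not np.isnan(m.dice):
            assert m.f1 == m.dice  # exact algebraic identity in the binary case
        if not (np.isnan(m.dice) or np.isnan(m.jaccard)):
            assert m.dice == pytest.approx(2 * m.jaccard / (1 + m.jaccard), abs=1e-12)
        for v in m.as_dict().values():
            assert np.isnan(v) or 0.0 <= v <= 1.0


class TestMulticlassConfusion:
    def _tooth(self, label, x0, x1, y0=0.0, y1=4.0):
        return PolygonContour(label, [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])

    def test_identical_scenes_no_errors_any_role(self, synthetic_truth):
        _, truth = synthetic_truth
        for role in ("bone", "cej", "teeth"):
            c = ev.multiclass_confusion(truth.scene, truth.scene, role)
            assert c.fp == 0 and c.fn == 0
            assert c.tp > 0

    def test_wrong_fdi_label_counts_fp_and_fn(self):
        poly = self._tooth("11", 0, 2)
        truth = AnnotationScene(4, 4, teeth={11: poly})
        pred = AnnotationScene(4, 4, teeth={12: PolygonContour("12", poly.points)})
        c = ev.multiclass_confusion(pred, truth, "teeth")
        area = 8  # 2x4 pixels
        assert c.tp == 0
        assert c.fp == area and c.fn == area

    def test_two_class_toy_equals_hand_enumeration(self):
        truth = AnnotationScene(
            4, 4, teeth={11: self._tooth("11", 0, 2), 12: self._tooth("12", 2, 4)}
        )
        pred = AnnotationScene(
            4, 4, teeth={11: self._tooth("11", 0, 2), 12: self._tooth("12", 1, 4)}
        )
        c = ev.multiclass_confusion(pred, truth, "teeth")
        # class 11: tp=8 tn=8; class 12: tp=8 fp=4 tn=4
        assert (c.tp, c.fp, c.fn, c.tn) == (16, 4, 0, 12)
        assert c.total == 2 * 16

    def test_dimension_mismatch_rejected(self):
        a = AnnotationScene(4, 4)
        b = AnnotationScene(5, 4)
        with pytest.raises(ValueError):
            ev.multiclass_confusion(a, b, "bone")


class TestBootstrapCI:
    def test_identical_images_zero_width_ci(self):
        counts = [ev.ConfusionCounts(40, 10, 10, 40)] * 6
        r = ev.bootstrap_ci(counts, n_iterations=200, seed=0)
        for name in ev.METRIC_NAMES:
            assert r.ci_low[name] == pytest.approx(r.ci_high[name])
            assert r.ci_low[name] == pytest.approx(
                getattr(r.point_estimate, name)
            )

    def test_single_image_zero_width_at_its_value(self):
        r = ev.bootstrap_ci([ev.ConfusionCounts(30, 10, 5, 55)], 100, seed=1)
        assert r.ci_low["dice"] == r.ci_high["dice"]

    def test_two_image_dice_enumerated_distribution(self):
        # images with dice 0 and 1 and equal pixel totals: the four equally
        # likely resamples give pooled dice {0, 0.5, 1} with weights
        # {0.25, 0.5, 0.25}
        a = ev.ConfusionCounts(0, 100, 100, 0)
        b = ev.ConfusionCounts(100, 0, 0, 100)
        r = ev.bootstrap_ci([a, b], n_iterations=1000, seed=3)
        dist = r.distributions["dice"]
        values, counts = np.unique(dist, return_counts=True)
        assert set(values.tolist()) <= {0.0, 0.5, 1.0}
        freq = dict(zip(values.tolist(), counts / dist.size))
        assert freq.get(0.0, 0) == pytest.approx(0.25, abs=0.05)
        assert freq.get(0.5, 0) == pytest.approx(0.50, abs=0.05)
        assert freq.get(1.0, 0) == pytest.approx(0.25, abs=0.05)
        assert (r.ci_low["dice"], r.ci_high["dice"]) == (0.0, 1.0)

    def test_seeded_reproducibility_and_order_invariant_estimate(self):
        counts = [
            ev.ConfusionCounts(10, 2, 3, 85),
            ev.ConfusionCounts(40, 9, 1, 50),
            ev.ConfusionCounts(25, 5, 5, 65),
        ]
        r1 = ev.bootstrap_ci(counts, 300, seed=9)
        r2 = ev.bootstrap_ci(counts, 300, seed=9)
        assert r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high
        r3 = ev.bootstrap_ci(counts[::-1], 300, seed=9)
        assert r3.point_estimate == r1.point_estimate

    def test_ci_brackets_bootstrap_median(self):
        counts = [
            ev.ConfusionCounts(10, 2, 3, 85),
            ev.ConfusionCounts(40, 9, 1, 50),
        ]
        r = ev.bootstrap_ci(counts, 500, seed=2)
        for name in ev.METRIC_NAMES:
            med = float(np.median(r.distributions[name]))
            assert r.ci_low[name] <= med <= r.ci_high[name]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_ci([], 10, seed=0)


class TestStageDistribution:
    def test_study_counts_statistic_and_p(self):
        stat, p = ev.stage_distribution_test([185, 161, 154])
        assert stat == pytest.approx(3.17, abs=0.01)
        assert p == pytest.approx(0.205, abs=0.001)

    def test_equal_counts_give_zero_statistic(self):
        stat, p = ev.stage_distribution_test([100, 100, 100])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.stage_distribution_test([500])
        with pytest.raises(ValueError):
            ev.stage_distribution_test([0, 0, 0])

    def test_stage_shares_percentages(self):
        assert ev.stage_shares([185, 161, 154]) == pytest.approx([37.0, 32.2, 30.8])
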