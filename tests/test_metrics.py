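"""Evaluation metrics against brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attr2unet.metrics import (
    ConfusionCounts,
    confusion,
    fold_summary,
    kruskal_wallis,
    pr_curve,
    radar_percentage,
    relative_difference,
    scalar_metrics,
)


class TestConfusion:
    def test_identical_masks(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[:2, :2] = 1
        c = confusion(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 12)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :] = 1
        b[1, :] = 1
        c = confusion(a, b)
        assert (c.tp, c.fp, c.fn) == (0, 4, 4)

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random((32, 32)) > 0.5
        t = rng.random((32, 32)) > 0.7
        c = confusion(p, t)
        tp = fp = fn = tn = 0
        for i in range(32):
            for j in range(32):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j]:
                    fp += 1
                elif t[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_shape_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestScalarMetrics:
    def test_balanced_counts(self):
        m = scalar_metrics(ConfusionCounts(2, 2, 2, 10))
        assert m["dsc"] == 0.5
        assert m["jaccard"] == pytest.approx(1 / 3)
        assert m["precision"] == 0.5
        assert m["sensitivity"] == 0.5

    def test_perfect_prediction(self):
        m = scalar_metrics(ConfusionCounts(5, 0, 0, 11))
        assert all(v == 1.0 for v in m.values())

    def test_empty_truth_empty_prediction_counts_as_perfect(self):
        m = scalar_metrics(ConfusionCounts(0, 0, 0, 16))
        assert m["dsc"] == 1.0 and m["jaccard"] == 1.0

    def test_empty_truth_nonempty_prediction_scores_zero(self):
        m = scalar_metrics(ConfusionCounts(0, 3, 0, 13))
        assert m["dsc"] == 0.0 and m["sensitivity"] == 0.0

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50), tn=st.integers(0, 50)
    )
    @settings(max_examples=120, deadline=None)
    def test_dice_jaccard_identity_and_ranges(self, tp, fp, fn, tn):
        m = scalar_metrics(ConfusionCounts(tp, fp, fn, tn))
        assert all(0.0 <= v <= 1.0 for v in m.values())
        j = m["jaccard"]
        assert m["dsc"] == pytest.approx(2 * j / (1 + j))
        fpr = (ConfusionCounts(tp, fp, fn, tn).fp / (tn + fp)) if (tn + fp) else 0.0
        assert m["specificity"] + fpr == pytest.approx(1.0)


class TestPRCurve:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        assert pr_curve(scores, truth.astype(bool)).auc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence_precision(self):
        scores = np.full(10, 0.5)
        truth = np.zeros(10, dtype=bool)
        truth[:3] = True
        curve = pr_curve(scores, truth)
        assert curve.precision[-1] == pytest.approx(0.3)
        assert curve.auc == pytest.approx(0.3)

    def test_matches_exhaustive_threshold_oracle(self):
        """10-pixel toy: trapezoid AUC over every distinct threshold computed
        by a brute-force loop must match to 1e-12."""
        rng = np.random.default_rng(4)
        scores = rng.random(10)
        truth = rng.random(10) > 0.5
        curve = pr_curve(scores, truth)
        pts = []
        for thr in sorted(set(scores), reverse=True):
            pred = scores >= thr
            tp = int((pred & truth).sum())
            fp = int((pred & ~truth).sum())
            pts.append((tp / truth.sum(), tp / (tp + fp)))
        recalls = [0.0] + [r for r, _ in pts]
        precisions = [pts[0][1]] + [p for _, p in pts]
        expected = np.trapezoid(precisions, recalls)
        assert curve.auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        truth = rng.random(200) > 0.6
        a = pr_curve(scores, truth).auc
        b = pr_curve(np.exp(3 * scores), truth).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_sklearn_points(self):
        from sklearn.metrics import precision_recall_curve

        rng = np.random.default_rng(6)
        scores = rng.random(50)
        truth = rng.random(50) > 0.5
        curve = pr_curve(scores, truth)
        skp, skr, _ = precision_recall_curve(truth.astype(int), scores)
        ours = {(round(r, 12), round(p, 12)) for r, p in zip(curve.recall[1:], curve.precision[1:])}
        # drop sklearn's appended (recall 0, precision 1) anchor; it also trims
        # operating points once full recall is reached, so compare as subset
        theirs = {(round(r, 12), round(p, 12)) for r, p in zip(skr[:-1], skp[:-1])}
        assert theirs <= ours

    def test_no_positive_pixels_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.array([0.1, 0.2]), np.array([False, False]))


class TestRadarPercentage:
    def test_endpoints(self):
        assert radar_percentage(0.816, 0.816) == pytest.approx(100.0)
        assert radar_percentage(0.5, 0.816) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert radar_percentage(0.790, 0.816) == pytest.approx(91.77, abs=0.01)

    def test_degenerate_maximum_rejected(self):
        with pytest.raises(ValueError):
            radar_percentage(0.4, 0.5)


class TestRelativeDifference:
    def test_lower_comparator_is_negative(self):
        assert relative_difference(0.816, 0.790) == pytest.approx(-3.19)

    def test_higher_comparator_is_positive(self):
        assert relative_difference(0.814, 0.903) == pytest.approx(9.86)

    def test_equal_inputs_zero(self):
        assert relative_difference(0.7, 0.7) == 0.0

    def test_symmetric_magnitude(self):
        assert relative_difference(0.6, 0.8) == pytest.approx(-relative_difference(0.8, 0.6))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(0.0, 1.0)


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        """H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 (no ties here)."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        n = 6
        ranks = {v: i + 1 for i, v in enumerate(sorted(sum(groups, [])))}
        h_oracle = 12.0 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2 for g in groups
        )
        from scipy.stats import chi2

        p_oracle = float(chi2.sf(h_oracle, df=1))
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(h_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.random(8)), list(rng.random(8) + 0.3)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            h, p = kruskal_wallis([list(rng.random(5)), list(rng.random(5))])
            assert 0.0 < p <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestFoldSummary:
    def test_published_cross_validation_rows(self):
        mean, _ = fold_summary([0.8020, 0.8044, 0.8030, 0.7552, 0.7923])
        assert mean == pytest.approx(0.7914)
        mean2, _ = fold_summary([0.8080, 0.7870, 0.8023, 0.7295, 0.7627])
        assert mean2 == pytest.approx(0.7779)

    def test_single_value(self):
        assert fold_summary([0.5]) == (0.5, 0.0)

    def test_sample_std_convention(self):
        vals = [0.1, 0.2, 0.3]
        _, std = fold_summary(vals)
        assert std == pytest.approx(round(float(np.std(vals, ddof=1)), 4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fold_summary([])
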