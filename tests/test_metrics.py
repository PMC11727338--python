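import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from attnseg import metrics as M

from conftest import random_mask_pairs
from oracles import auc_pairwise, confusion_bruteforce, dsc_bruteforce, hd95_bruteforce


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), dtype=np.uint8)
        truth[:2, :5] = 1
        c = M.confusion(truth, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (10, 0, 90, 0)

    def test_all_false_positives(self):
        c = M.confusion(np.ones((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8))
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 16, 0, 0)

    def test_matches_bruteforce_on_random_pairs(self):
        for pred, truth in random_mask_pairs(20, size=8, seed=5):
            c = M.confusion(pred, truth)
            assert (c.tp, c.fp, c.tn, c.fn) == confusion_bruteforce(pred, truth)
            assert c.total == pred.size

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            M.confusion(np.full((2, 2), 3), np.zeros((2, 2)))


class TestDsc:
    def test_identical_nonempty_is_one(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[2:4, 2:4] = 1
        assert M.dsc(m, m) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert M.dsc(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |A|=4, |B|=2, |A∩B|=2 -> 2*2/6
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, :4] = 1
        b[0, :2] = 1
        assert M.dsc(a, b) == pytest.approx(2 * 2 / 6)

    def test_empty_conventions(self):
        empty = np.zeros((3, 3), dtype=np.uint8)
        one = empty.copy()
        one[1, 1] = 1
        assert M.dsc(empty, empty) == 1.0
        assert M.dsc(one, empty) == 0.0
        assert M.dsc(empty, one) == 0.0


class TestPrecisionRecallAccuracy:
    def test_hand_values(self):
        c = M.ConfusionCounts(tp=2, fp=2, tn=0, fn=0)
        assert M.precision(c) == 0.5
        c = M.ConfusionCounts(tp=5, fp=0, tn=0, fn=0)
        assert M.recall(c) == 1.0
        c = M.ConfusionCounts(tp=3, fp=1, tn=10, fn=2)
        assert M.accuracy(c) == pytest.approx(13 / 16)

    def test_zero_denominator_sentinel(self):
        c = M.ConfusionCounts(tp=0, fp=0, tn=4, fn=0)
        assert M.precision(c) == 0.0
        assert M.recall(c) == 0.0

    def test_f1_identity_with_dsc(self):
        # DSC == 2PR/(P+R) on binary masks, exactly
        for pred, truth in random_mask_pairs(50, size=16, seed=9):
            c = M.confusion(pred, truth)
            p, r = M.precision(c), M.recall(c)
            if p + r == 0:
                continue
            assert abs(M.dsc(pred, truth) - 2 * p * r / (p + r)) <= 1e-12


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        assert M.roc_auc(probs, truth) == 1.0

    def test_constant_scores_give_half(self):
        probs = np.full(8, 0.3)
        truth = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        assert M.roc_auc(probs, truth) == 0.5

    def test_toy_vector_matches_pairwise_oracle(self):
        probs = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.1])
        truth = np.array([1, 1, 0, 1, 0, 0])
        assert M.roc_auc(probs, truth) == pytest.approx(
            auc_pairwise(probs, truth), abs=1e-12
        )

    def test_matches_pairwise_oracle_and_sklearn_on_random_maps(self, rng):
        for _ in range(25):
            probs = rng.random(40)
            truth = (rng.random(40) < 0.4).astype(np.uint8)
            if truth.sum() in (0, 40):
                continue
            ours = M.roc_auc(probs, truth)
            assert ours == pytest.approx(auc_pairwise(probs, truth), abs=1e-9)
            assert ours == pytest.approx(roc_auc_score(truth, probs), abs=1e-9)

    def test_single_class_truth_raises(self):
        with pytest.raises(ValueError, match="single class"):
            M.roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(30)
        truth = (rng.random(30) < 0.5).astype(np.uint8)
        if truth.sum() in (0, 30):
            return
        base = M.roc_auc(probs, truth)
        for f in (lambda p: p**3, lambda p: 1 / (1 + np.exp(-5 * p)), lambda p: 2 * p + 1):
            assert M.roc_auc(f(probs), truth) == pytest.approx(base, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        probs = rng.random(50)
        truth = (rng.random(50) < 0.5).astype(np.uint8)
        pts = M.roc_curve(probs, truth)
        np.testing.assert_array_equal(pts[0], [0, 0])
        np.testing.assert_array_equal(pts[-1], [1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0)


def square_mask(size, top, left, side):
    m = np.zeros((size, size), dtype=np.uint8)
    m[top : top + side, left : left + side] = 1
    return m


class TestHd95:
    def test_identical_masks_zero(self):
        m = square_mask(12, 3, 3, 5)
        assert M.hd95(m, m) == 0.0

    def test_two_single_pixels_five_apart(self):
        a = np.zeros((12, 12), dtype=np.uint8)
        b = np.zeros((12, 12), dtype=np.uint8)
        a[3, 2] = 1
        b[3, 7] = 1
        assert M.hd95(a, b) == 5.0

    def test_shifted_square_matches_bruteforce(self):
        a = square_mask(20, 4, 4, 8)
        b = square_mask(20, 7, 4, 8)  # shifted 3 px down
        assert M.hd95(a, b) == pytest.approx(hd95_bruteforce(a, b), abs=1e-9)

    def test_matches_bruteforce_on_random_blobs(self):
        kept = 0
        for pred, truth in random_mask_pairs(30, size=12, p=0.25, seed=17):
            if pred.sum() == 0 or truth.sum() == 0:
                continue
            kept += 1
            assert M.hd95(pred, truth) == pytest.approx(
                hd95_bruteforce(pred, truth), abs=1e-9
            )
        assert kept >= 20

    def test_symmetry_and_translation_invariance(self):
        a = square_mask(24, 4, 4, 6)
        b = square_mask(24, 8, 6, 5)
        assert M.hd95(a, b) == M.hd95(b, a)
        a2 = square_mask(24, 9, 10, 6)
        b2 = square_mask(24, 13, 12, 5)
        assert M.hd95(a, b) == pytest.approx(M.hd95(a2, b2), abs=1e-12)

    def test_empty_mask_raises(self):
        m = square_mask(8, 2, 2, 3)
        with pytest.raises(ValueError, match="empty"):
            M.hd95(np.zeros((8, 8), dtype=np.uint8), m)
        with pytest.raises(ValueError, match="empty"):
            M.hd95(m, np.zeros((8, 8), dtype=np.uint8))


class TestAggregateRuns:
    def test_identical_runs_zero_spread(self):
        runs = [{"dsc": 0.9, "recall": 0.8}] * 4
        agg = M.aggregate_runs(runs)
        assert agg.loc["dsc", "sd"] == 0.0
        assert agg.loc["dsc", "ci95_half_width"] == 0.0

    def test_two_run_hand_values(self):
        agg = M.aggregate_runs([{"dsc": 0.90}, {"dsc": 0.92}])
        assert agg.loc["dsc", "mean"] == pytest.approx(0.91)
        assert agg.loc["dsc", "sd"] == pytest.approx(0.014142135, abs=1e-8)

    def test_ten_runs_t_interval(self, rng):
        vals = 0.9 + 0.02 * rng.standard_normal(10)
        agg = M.aggregate_runs([{"m": v} for v in vals])
        t9 = stats.t.ppf(0.975, 9)  # tabulated 2.262...
        assert t9 == pytest.approx(2.2621572, abs=1e-6)
        expected = t9 * np.std(vals, ddof=1) / np.sqrt(10)
        assert agg.loc["m", "ci95_half_width"] == pytest.approx(expected, abs=1e-12)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            M.aggregate_runs([{"dsc": 0.9}])

    def test_bootstrap_option_runs(self):
        agg = M.aggregate_runs([{"d": 0.8}, {"d": 0.9}, {"d": 0.85}], method="bootstrap")
        assert agg.loc["d", "ci95_half_width"] >= 0.0


class TestEvaluateMasks:
    def test_field_set_and_nan_conventions(self):
        truth = square_mask(16, 4, 4, 6)
        probs = truth * 0.9 + 0.05
        pred = (probs >= 0.5).astype(np.uint8)
        out = M.evaluate_masks(pred, truth, probs=probs)
        assert set(out) == {"dsc", "precision", "recall", "accuracy", "hd95", "auc"}
        assert out["dsc"] == 1.0 and out["hd95"] == 0.0
        empty = np.zeros((16, 16), dtype=np.uint8)
        out = M.evaluate_masks(empty, truth, probs=np.full((16, 16), 0.2))
        assert np.isnan(out["hd95"])
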