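import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import demuxsig as dx
from oracles import auc_pair_count, homogeneity_completeness_bruteforce


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = dx.classification_metrics(y, y, 3)
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.f1, [1.0, 1.0, 1.0])
        assert np.trace(rep.confusion) == 6

    def test_hand_filled_confusion(self):
        # y_true=[0,0,1,1], y_pred=[0,1,1,1]
        rep = dx.classification_metrics([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert rep.accuracy == 0.75
        np.testing.assert_allclose(rep.precision, [1.0, 2 / 3])
        np.testing.assert_allclose(rep.recall, [0.5, 1.0])
        np.testing.assert_allclose(rep.f1, [2 / 3, 0.8])
        assert abs(rep.macro_f1 - (2 / 3 + 0.8) / 2) < 1e-12

    def test_never_predicted_class_flagged_zero(self):
        rep = dx.classification_metrics([0, 1, 2], [0, 1, 1], 3)
        assert rep.precision[2] == 0.0
        assert 2 in rep.undefined_precision

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dx.classification_metrics([0, 1], [0], 2)

    def test_balanced_accuracy_equals_macro_recall(self, rng):
        # with exactly balanced classes micro accuracy == macro recall
        y_true = np.repeat(np.arange(4), 25)
        y_pred = rng.randint(0, 4, size=100)
        rep = dx.classification_metrics(y_true, y_pred, 4)
        assert abs(rep.accuracy - rep.macro_recall) < 1e-12


class TestRocAuc:
    def test_perfect_and_tied(self):
        y = np.array([1, 1, 0, 0])
        scores = np.stack([1 - np.array([0.9, 0.8, 0.4, 0.2]),
                           np.array([0.9, 0.8, 0.4, 0.2])], axis=1)
        assert dx.roc_auc_ovr(y, scores, 1) == 1.0
        flat = np.full((4, 2), 0.5)
        assert dx.roc_auc_ovr(y, flat, 1) == 0.5

    def test_hand_counted_pairs(self):
        y = np.array([1, 0, 1, 0])
        s = np.zeros((4, 2))
        s[:, 1] = [0.8, 0.5, 0.3, 0.1]
        assert abs(dx.roc_auc_ovr(y, s, 1) - 0.75) < 1e-12

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            dx.roc_auc_ovr(np.array([1, 1]), np.ones((2, 2)), 1)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pair_enumeration(self, seed):
        r = np.random.RandomState(seed)
        n = r.randint(4, 40)
        y = r.randint(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # quantized scores force ties through the tie-handling path
        s = np.zeros((n, 2))
        s[:, 1] = r.randint(0, 5, size=n) / 4.0
        expected = auc_pair_count(s[y == 1, 1], s[y == 0, 1])
        assert abs(dx.roc_auc_ovr(y, s, 1) - expected) < 1e-9


class TestHomogeneityCompleteness:
    def test_identity_clustering(self):
        y = [0, 0, 1, 1, 2]
        h, c = dx.homogeneity_completeness(y, y)
        assert h == pytest.approx(1.0) and c == pytest.approx(1.0)

    def test_singleton_clusters(self):
        # every cluster pure -> h=1; classes split over 2 clusters each:
        # c = 1 - ln2/ln4 = 0.5
        h, c = dx.homogeneity_completeness([0, 0, 1, 1], [0, 1, 2, 3])
        assert h == pytest.approx(1.0)
        assert c == pytest.approx(0.5)

    def test_single_cluster_limit(self):
        h, c = dx.homogeneity_completeness([0, 0, 1, 1], [0, 0, 0, 0])
        assert h == pytest.approx(0.0) and c == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_bruteforce_entropy(self, seed):
        r = np.random.RandomState(seed)
        n = r.randint(2, 50)
        y = r.randint(0, r.randint(1, 6), size=n)
        cl = r.randint(0, r.randint(1, 6), size=n)
        h, c = dx.homogeneity_completeness(y, cl)
        hb, cb = homogeneity_completeness_bruteforce(y, cl)
        assert abs(h - hb) < 1e-9 and abs(c - cb) < 1e-9

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_cluster_relabeling(self, seed):
        r = np.random.RandomState(seed)
        n = r.randint(4, 30)
        y = r.randint(0, 3, size=n)
        cl = r.randint(0, 4, size=n)
        perm = r.permutation(4)
        rep1 = dx.majority_vote_map(y, cl)
        rep2 = dx.majority_vote_map(y, perm[cl])
        assert rep1.homogeneity == pytest.approx(rep2.homogeneity)
        assert rep1.completeness == pytest.approx(rep2.completeness)
        assert rep1.mapped_accuracy == pytest.approx(rep2.mapped_accuracy)


class TestMajorityVote:
    def test_worked_example(self):
        # cluster A: true [0,0,1]; cluster B: true [1,1] -> accuracy 4/5
        y = [0, 0, 1, 1, 1]
        cl = [0, 0, 0, 1, 1]
        rep = dx.majority_vote_map(y, cl)
        assert rep.cluster_to_label == {0: 0, 1: 1}
        assert rep.mapped_accuracy == pytest.approx(0.8)

    def test_identity_and_single_cluster(self):
        y = [0, 0, 0, 1]
        assert dx.majority_vote_map(y, y).mapped_accuracy == 1.0
        rep = dx.majority_vote_map(y, [0, 0, 0, 0])
        assert rep.cluster_to_label == {0: 0}
        assert rep.mapped_accuracy == pytest.approx(0.75)

    def test_tie_goes_to_lowest_label(self):
        rep = dx.majority_vote_map([1, 0], [0, 0])
        assert rep.cluster_to_label == {0: 0}


class TestEvaluateJoin:
    def _truth(self):
        sigs = [dx.RawSignal(f"r{i}", np.array([1.0, 2.0]), label=i % 2)
                for i in range(4)]
        return dx.SignalSet(sigs, n_classes=2)

    def test_join_order_independent(self):
        truth = self._truth()
        ids = ["r2", "r0", "r3", "r1"]
        preds = np.array([0, 0, 1, 1])
        rep1, _ = dx.evaluate(ids, preds, None, truth)
        rep2, _ = dx.evaluate(list(reversed(ids)), preds[::-1], None, truth)
        assert rep1.accuracy == rep2.accuracy
        np.testing.assert_array_equal(rep1.confusion, rep2.confusion)

    def test_missing_read_errors(self):
        truth = self._truth()
        with pytest.raises(ValueError, match="r3"):
            dx.evaluate(["r0", "r1", "r2"], np.array([0, 1, 0]), None, truth)

    def test_cluster_protocol_activates(self):
        truth = self._truth()
        ids = ["r0", "r1", "r2", "r3"]
        clusters = {rid: i % 2 for i, rid in enumerate(ids)}
        rep, clus = dx.evaluate(ids, np.array([0, 1, 0, 1]), None, truth,
                                clusters=clusters)
        assert rep.accuracy == 1.0
        assert clus is not None and clus.mapped_accuracy == 1.0
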