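import itertools

import numpy as np
import pytest

from csifcm import evaluate, match_clusters, overall_accuracy, segment_metrics, tpr_fpr
from csifcm.evaluation import apply_mapping, contingency_table


def brute_force_matching(table):
    """Enumerate all permutations and return the best total overlap."""
    c = table.shape[0]
    best, best_perm = -1, None
    for perm in itertools.permutations(range(c)):
        total = sum(table[i, perm[i]] for i in range(c))
        if total > best:
            best, best_perm = total, perm
    return best, best_perm


class TestMatchClusters:
    def test_identical_maps_identity_mapping(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        assert match_clusters(labels, labels, 3) == {0: 0, 1: 1, 2: 2}

    def test_swapped_labels_swapped_mapping(self):
        pred = np.array([1, 0, 1, 0])
        true = np.array([0, 1, 0, 1])
        assert match_clusters(pred, true, 2) == {0: 1, 1: 0}

    def test_three_cluster_table_matches_brute_force(self):
        # contingency {{5,0,1},{0,4,0},{2,0,6}}: best assignment is identity (15)
        pred = np.repeat([0, 0, 1, 2, 2], [5, 1, 4, 2, 6])
        true = np.concatenate([[0] * 5, [2], [1] * 4, [0] * 2, [2] * 6])
        table = contingency_table(pred, true, 3)
        np.testing.assert_array_equal(table, [[5, 0, 1], [0, 4, 0], [2, 0, 6]])
        mapping = match_clusters(pred, true, 3)
        best, best_perm = brute_force_matching(table)
        assert best == 15
        assert mapping == dict(enumerate(best_perm))

    def test_random_maps_match_brute_force(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, 60)
            true = rng.integers(0, 4, 60)
            mapping = match_clusters(pred, true, 4)
            table = contingency_table(pred, true, 4)
            achieved = sum(table[i, j] for i, j in mapping.items())
            best, _ = brute_force_matching(table)
            assert achieved == best

    def test_missing_classes_padded(self):
        pred = np.array([0, 0, 0])  # only one predicted cluster
        true = np.array([0, 1, 2])
        mapping = match_clusters(pred, true, 3)
        assert sorted(mapping) == [0, 1, 2]
        assert sorted(mapping.values()) == [0, 1, 2]


class TestSegmentMetrics:
    def test_perfect_overlap(self):
        s = np.array([1, 1, 0, 0], dtype=bool)
        assert segment_metrics(s, s) == (1.0, 0.0, 0.0)

    def test_half_sized_subset(self):
        s1 = np.ones(10, dtype=bool)
        s2 = np.zeros(10, dtype=bool)
        s2[:5] = True
        rho, fpr, fnr = segment_metrics(s1, s2)
        assert (rho, fpr, fnr) == (pytest.approx(2 / 3), 0.0, 0.5)

    def test_hand_arithmetic_example(self):
        # |S1|=10, |S2|=14, |S1 & S2|=8 -> fpr 0.6, fnr 0.2, rho 16/24
        s1 = np.zeros(30, dtype=bool)
        s1[:10] = True
        s2 = np.zeros(30, dtype=bool)
        s2[2:16] = True  # overlap 8, extras 6
        rho, fpr, fnr = segment_metrics(s1, s2)
        assert rho == pytest.approx(16 / 24)
        assert fpr == pytest.approx(0.6)
        assert fnr == pytest.approx(0.2)

    def test_fpr_can_exceed_one(self):
        # prediction 4x larger than the ground-truth segment
        s1 = np.zeros(20, dtype=bool)
        s1[:4] = True
        s2 = np.zeros(20, dtype=bool)
        s2[:16] = True
        _, fpr, _ = segment_metrics(s1, s2)
        assert fpr == pytest.approx(3.0)

    def test_empty_ground_truth_flagged_undefined(self):
        out = segment_metrics(np.zeros(5, dtype=bool), np.ones(5, dtype=bool))
        assert all(np.isnan(v) for v in out)

    def test_rho_symmetric_fpr_fnr_not(self, rng):
        s1 = rng.random(50) > 0.5
        s2 = rng.random(50) > 0.5
        rho_a, fpr_a, fnr_a = segment_metrics(s1, s2)
        rho_b, fpr_b, fnr_b = segment_metrics(s2, s1)
        assert rho_a == pytest.approx(rho_b)
        # swapping roles exchanges surplus and omission errors
        assert fpr_a * s1.sum() == pytest.approx(fnr_b * s2.sum())

    def test_fnr_complements_recall(self, rng):
        s1 = rng.random(40) > 0.3
        s2 = rng.random(40) > 0.5
        _, _, fnr = segment_metrics(s1, s2)
        recall = (s1 & s2).sum() / s1.sum()
        assert fnr + recall == pytest.approx(1.0)


class TestTprFpr:
    def test_perfect_prediction(self):
        s = np.array([1, 0, 1], dtype=bool)
        assert tpr_fpr(s, s) == (1.0, 0.0)

    def test_definition_arithmetic(self):
        # |S1|=10 of 100, TP=8, FP=6 -> TPR 0.8, FPR 6/90
        s1 = np.zeros(100, dtype=bool)
        s1[:10] = True
        s2 = np.zeros(100, dtype=bool)
        s2[2:16] = True
        tpr, fpr = tpr_fpr(s1, s2, 100)
        assert tpr == pytest.approx(0.8)
        assert fpr == pytest.approx(6 / 90)

    def test_positives_denominator_switch(self):
        s1 = np.zeros(100, dtype=bool)
        s1[:10] = True
        s2 = np.zeros(100, dtype=bool)
        s2[2:16] = True
        _, fpr = tpr_fpr(s1, s2, 100, fpr_denominator="positives")
        assert fpr == pytest.approx(0.6)

    def test_empty_prediction(self):
        s1 = np.array([1, 1, 0], dtype=bool)
        assert tpr_fpr(s1, np.zeros(3, dtype=bool)) == (0.0, 0.0)

    def test_all_positive_truth_fpr_undefined(self):
        s1 = np.ones(4, dtype=bool)
        _, fpr = tpr_fpr(s1, s1)
        assert np.isnan(fpr)


class TestOverallAccuracy:
    def test_identical_maps(self):
        labels = np.array([[0, 1], [2, 3]])
        mapping = {i: i for i in range(4)}
        assert overall_accuracy(labels, labels, mapping) == 1.0

    def test_one_wrong_pixel_of_100(self):
        true = np.zeros(100, dtype=int)
        pred = true.copy()
        pred[0] = 1
        assert overall_accuracy(pred, true, {0: 0, 1: 1}) == pytest.approx(0.99)

    def test_confusion_table_count(self):
        # confusion {{3,1},{0,4}} on 8 pixels -> 7/8
        true = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        pred = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert overall_accuracy(pred, true, {0: 0, 1: 1}) == pytest.approx(7 / 8)

    def test_invariant_to_consistent_relabeling(self, rng):
        true = rng.integers(0, 3, 50)
        pred = rng.integers(0, 3, 50)
        mapping = match_clusters(pred, true, 3)
        acc = overall_accuracy(pred, true, mapping)
        perm = np.array([2, 0, 1])
        pred2, true2 = perm[pred], perm[true]
        mapping2 = match_clusters(pred2, true2, 3)
        assert overall_accuracy(pred2, true2, mapping2) == pytest.approx(acc)


class TestEvaluateReport:
    def test_report_shape_and_csv(self, tmp_path):
        true = np.array([[0, 0, 1, 1], [2, 2, 3, 3]])
        pred = np.array([[1, 1, 0, 0], [3, 3, 2, 2]])  # swapped pairs
        report = evaluate(pred, true, 4)
        assert report.overall_accuracy == 1.0
        assert list(report.per_segment["segment"]) == [0, 1, 2, 3]
        assert (report.per_segment["rho"] == 1.0).all()
        out = tmp_path / "report.csv"
        report.to_csv(out)
        text = out.read_text()
        assert "overall" in text

    def test_mapping_applied_before_metrics(self):
        true = np.array([0, 0, 1, 1, 1])
        pred = np.array([1, 1, 0, 0, 0])
        report = evaluate(pred, true, 2)
        assert report.mapping == {0: 1, 1: 0}
        np.testing.assert_array_equal(apply_mapping(pred, report.mapping), true)
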