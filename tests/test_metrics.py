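"""Evaluation metrics vs hand counts and exhaustive-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsnhv.metrics import (dice_coef, aji, match_instances, panoptic_quality,
                           detection_f1, classification_score, evaluate_pair,
                           MatchResult)
from _oracles import dice_oracle, aji_oracle, pq_oracle, random_instance_map


def _map_from_rows(rows):
    return np.array(rows, dtype=np.int32)


class TestDice:
    def test_identical_nonempty(self):
        m = _map_from_rows([[1, 1], [0, 1]])
        assert dice_coef(m, m) == 1.0

    def test_half_overlap_hand_count(self):
        x = _map_from_rows([[1, 1, 0, 0]])
        y = _map_from_rows([[0, 1, 1, 0]])
        assert dice_coef(x, y) == pytest.approx(0.5)

    def test_disjoint_and_empty_conventions(self):
        x = _map_from_rows([[1, 0], [0, 0]])
        y = _map_from_rows([[0, 0], [0, 1]])
        assert dice_coef(x, y) == 0.0
        z = np.zeros((2, 2), dtype=np.int32)
        assert dice_coef(z, z) == 1.0


class TestAJI:
    def test_identical_maps(self):
        m = random_instance_map(np.random.default_rng(0))
        assert aji(m, m) == pytest.approx(1.0)

    def test_partial_overlap_hand_enumeration(self):
        # 1 gt of 4 px, 1 pred of 4 px, overlapping 2 px: 2 / 6
        gt = _map_from_rows([[1, 1, 1, 1, 0, 0]])
        pred = _map_from_rows([[0, 0, 1, 1, 1, 1]])
        assert aji(gt, pred) == pytest.approx(1 / 3)

    def test_spurious_prediction_enters_union(self):
        gt = np.zeros((4, 10), dtype=np.int32)
        gt[0, :10] = 1                       # 10 px instance
        pred = gt.copy()
        pred[2, :5] = 2                      # extra 5 px false positive
        assert aji(gt, pred) == pytest.approx(10 / 15)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), dtype=np.int32)
        something = empty.copy()
        something[1, 1] = 1
        assert aji(empty, empty) == 1.0
        assert aji(empty, something) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            aji(np.zeros((2, 2), dtype=int), np.zeros((3, 2), dtype=int))


class TestPanopticQuality:
    def test_perfect_prediction(self):
        m = random_instance_map(np.random.default_rng(1))
        assert panoptic_quality(m, m) == (1.0, 1.0, 1.0)

    def test_single_pair_above_threshold(self):
        gt = np.zeros((1, 10), dtype=np.int32)
        gt[0, :5] = 1
        pred = np.zeros((1, 10), dtype=np.int32)
        pred[0, 2:5] = 1                     # IoU = 3/5 = 0.6
        dq, sq, pq = panoptic_quality(gt, pred)
        assert (dq, sq, pq) == (1.0, pytest.approx(0.6), pytest.approx(0.6))

    def test_single_pair_below_threshold_scores_zero(self):
        gt = np.zeros((1, 10), dtype=np.int32)
        gt[0, :5] = 1
        pred = np.zeros((1, 10), dtype=np.int32)
        pred[0, 3:8] = 1                     # IoU = 2/8 = 0.25
        dq, sq, pq = panoptic_quality(gt, pred)
        assert dq == 0.0 and pq == 0.0

    def test_both_empty_convention(self):
        empty = np.zeros((3, 3), dtype=np.int32)
        assert panoptic_quality(empty, empty) == (1.0, 1.0, 1.0)


class TestDetectionAndClassification:
    def test_detection_f1_counts(self):
        match = MatchResult(pairs=[(1, 1, 0.9), (2, 3, 0.8)],
                            unmatched_gt=[3], unmatched_pred=[2])
        assert detection_f1(match) == pytest.approx(2 / 3)

    def test_all_matched(self):
        match = MatchResult(pairs=[(1, 1, 1.0)], unmatched_gt=[],
                            unmatched_pred=[])
        assert detection_f1(match) == 1.0

    def test_no_predictions(self):
        match = MatchResult(pairs=[], unmatched_gt=[1, 2], unmatched_pred=[])
        assert detection_f1(match) == 0.0

    def test_classification_score_hand_case(self):
        # 2 matched pairs of type t, both typed correctly, 1 missed gt
        match = MatchResult(pairs=[(1, 1, 0.9), (2, 2, 0.9)],
                            unmatched_gt=[3], unmatched_pred=[])
        fct = classification_score(match, {1: 1, 2: 1, 3: 1}, {1: 1, 2: 1}, 1)
        assert fct == pytest.approx(0.8)     # 2*2 / (2*2 + 0 + 1)

    def test_perfect_detection_and_typing(self):
        match = MatchResult(pairs=[(1, 1, 1.0), (2, 2, 1.0)],
                            unmatched_gt=[], unmatched_pred=[])
        gt_types = {1: 1, 2: 2}
        for t in (1, 2):
            assert classification_score(match, gt_types, gt_types, t) == 1.0

    def test_vacuous_case_scores_one(self):
        match = MatchResult(pairs=[], unmatched_gt=[], unmatched_pred=[])
        assert classification_score(match, {}, {}, 1) == 1.0


@pytest.fixture(scope="module")
def random_pairs():
    rng = np.random.default_rng(2024)
    return [(random_instance_map(rng), random_instance_map(rng))
            for _ in range(100)]


class TestOracleEquivalence:
    """Exhaustive set-enumeration oracles agree to 1e-12 on random maps."""

    def test_dice_aji_pq_match_brute_force(self, random_pairs):
        for gt, pred in random_pairs:
            assert dice_coef(gt, pred) == pytest.approx(
                dice_oracle(gt, pred), abs=1e-12)
            assert aji(gt, pred) == pytest.approx(
                aji_oracle(gt, pred), abs=1e-12)
            dq, sq, pq = panoptic_quality(gt, pred)
            odq, osq, opq = pq_oracle(gt, pred)
            assert dq == pytest.approx(odq, abs=1e-12)
            assert sq == pytest.approx(osq, abs=1e-12)
            assert pq == pytest.approx(opq, abs=1e-12)

    def test_label_permutation_invariance(self, random_pairs):
        rng = np.random.default_rng(5)
        for gt, pred in random_pairs[:20]:
            n = pred.max()
            if n < 2:
                continue
            perm = np.concatenate([[0], rng.permutation(n) + 1])
            permuted = perm[pred]
            assert aji(gt, permuted) == pytest.approx(aji(gt, pred), abs=1e-12)
            assert panoptic_quality(gt, permuted) == pytest.approx(
                panoptic_quality(gt, pred), abs=1e-12)
            assert dice_coef(gt, permuted) == dice_coef(gt, pred)

    def test_pq_bounded_by_factors(self, random_pairs):
        for gt, pred in random_pairs:
            dq, sq, pq = panoptic_quality(gt, pred)
            assert pq <= dq + 1e-12 and pq <= sq + 1e-12
            assert abs(pq - dq * sq) < 1e-12


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(min_value=0, max_value=2 ** 16))
def test_metric_bounds_hold_for_arbitrary_maps(seed):
    """All scores live in [0, 1] and PQ never exceeds its factors,
    whatever the instance geometry."""
    rng = np.random.default_rng(seed)
    gt = random_instance_map(rng, size=32, max_instances=4)
    pred = random_instance_map(rng, size=32, max_instances=4)
    a = aji(gt, pred)
    d = dice_coef(gt, pred)
    dq, sq, pq = panoptic_quality(gt, pred)
    for value in (a, d, dq, sq, pq):
        assert 0.0 <= value <= 1.0
    assert pq <= dq + 1e-12 and pq <= sq + 1e-12
    assert 0.0 <= detection_f1(match_instances(gt, pred)) <= 1.0


def test_evaluate_pair_bundles_everything(small_dataset):
    patch = small_dataset[0]
    gt_types = {int(l): int(np.bincount(
        patch.types[patch.instances == l]).argmax())
        for l in np.unique(patch.instances) if l}
    report = evaluate_pair(patch.instances, patch.instances,
                           gt_types, gt_types, 3)
    assert report.dice == report.aji == report.pq == report.fd == 1.0
    assert all(v == 1.0 for v in report.fct_per_type.values())
    assert abs(report.pq - report.dq * report.sq) < 1e-12
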