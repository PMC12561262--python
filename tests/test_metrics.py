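import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciof import ConfusionCounts, aggregate, confusion, slice_metrics
from ciof.metrics import SliceEval, evaluate_cohort

from conftest import make_slice
from ciof import Cohort


def brute_force_confusion(p, g):
    """Independent oracle: classify each pixel with an explicit double loop."""
    tp = fp = fn = tn = 0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] == 1 and g[i, j] == 1:
                tp += 1
            elif p[i, j] == 1 and g[i, j] == 0:
                fp += 1
            elif p[i, j] == 0 and g[i, j] == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_hand_worked_two_by_two(self):
        c = confusion(np.array([[1, 0], [1, 0]]), np.array([[1, 1], [0, 0]]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_perfect_prediction_has_no_errors(self):
        g = (np.random.default_rng(3).random((5, 7)) < 0.4).astype(np.uint8)
        c = confusion(g, g)
        assert c.fp == 0 and c.fn == 0 and c.tp == int(g.sum())

    def test_both_empty(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        c = confusion(z, z)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), dtype=np.uint8), np.zeros((2, 3), dtype=np.uint8))

    def test_matches_brute_force_oracle_and_conserves_pixels(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = (rng.random((8, 8)) < rng.uniform(0, 1)).astype(np.uint8)
            g = (rng.random((8, 8)) < rng.uniform(0, 1)).astype(np.uint8)
            c = confusion(p, g)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_confusion(p, g)
            assert c.total == 64


class TestSliceMetrics:
    def test_direct_substitution(self):
        ev = slice_metrics(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert ev.iou == pytest.approx(1 / 3)
        assert ev.dice == pytest.approx(1 / 2)
        assert ev.fnr == pytest.approx(1 / 2)
        assert ev.fpr == pytest.approx(1 / 2)
        assert not ev.degenerate

    def test_perfect_prediction(self):
        ev = slice_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=4))
        assert (ev.iou, ev.dice, ev.fnr) == (1.0, 1.0, 0.0)

    def test_both_empty_scores_perfect_by_convention(self):
        ev = slice_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=9))
        assert (ev.iou, ev.dice, ev.fnr, ev.fpr) == (1.0, 1.0, 0.0, 0.0)
        assert ev.degenerate

    def test_false_positives_on_empty_ground_truth_score_zero(self):
        ev = slice_metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=6))
        assert ev.iou == 0.0 and ev.dice == 0.0 and ev.fnr == 0.0
        assert ev.degenerate

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tn=st.integers(0, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_dice_iou_identity_and_bounds(self, tp, fp, fn, tn):
        ev = slice_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        for v in (ev.iou, ev.dice, ev.fnr, ev.fpr):
            assert 0.0 <= v <= 1.0
        if tp + fp + fn > 0:
            assert ev.dice == pytest.approx(2 * ev.iou / (1 + ev.iou), abs=1e-12)

    @given(tp=st.integers(0, 100), fp=st.integers(0, 100), fn=st.integers(1, 100))
    @settings(max_examples=100, derandomize=True)
    def test_converting_a_miss_to_a_hit_never_hurts(self, tp, fp, fn):
        before = slice_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=10))
        after = slice_metrics(ConfusionCounts(tp=tp + 1, fp=fp, fn=fn - 1, tn=10))
        assert after.iou >= before.iou and after.dice >= before.dice


class TestAggregate:
    def _evals(self, pairs):
        return [
            (pid, SliceEval(iou=v, dice=v, fnr=0.0, fpr=0.0,
                            counts=ConfusionCounts(1, 0, 0, 0), degenerate=False))
            for pid, v in pairs
        ]

    def test_patient_first_two_stage_mean(self):
        evals = self._evals([("A", 1.0), ("A", 0.0), ("B", 0.5)])
        out = aggregate(evals, scheme="per_patient_then_cohort")
        assert out["iou"] == pytest.approx(0.5)
        assert out["n_patients"] == 2 and out["n_slices"] == 3

    def test_pooled_slices_flat_mean(self):
        evals = self._evals([("A", 1.0), ("A", 0.0), ("B", 0.5)])
        out = aggregate(evals, scheme="pooled_slices")
        assert out["iou"] == pytest.approx(0.5)

    def test_schemes_agree_on_single_slice(self):
        evals = self._evals([("A", 0.7)])
        for scheme in ("per_patient_then_cohort", "pooled_slices"):
            assert aggregate(evals, scheme=scheme)["iou"] == pytest.approx(0.7)

    def test_schemes_differ_under_unbalanced_patients(self):
        evals = self._evals([("A", 1.0), ("A", 1.0), ("A", 1.0), ("B", 0.0)])
        nested = aggregate(evals, scheme="per_patient_then_cohort")["iou"]
        pooled = aggregate(evals, scheme="pooled_slices")["iou"]
        assert nested == pytest.approx(0.5) and pooled == pytest.approx(0.75)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no evaluable"):
            aggregate([], scheme="pooled_slices")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            aggregate(self._evals([("A", 1.0)]), scheme="bogus")


class TestEvaluateCohort:
    def _cohort(self):
        gt_pos = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        gt_empty = np.zeros((2, 2), dtype=np.uint8)
        return Cohort(slices=[
            make_slice("A", "S0", gt_pos, [gt_pos]),
            make_slice("A", "S1", gt_empty, [gt_empty]),
        ])

    def test_degenerate_slices_excluded_by_default(self):
        cohort = self._cohort()
        fused = {(s.patient_id, s.slice_id): s.ground_truth for s in cohort.slices}
        table, summary = evaluate_cohort(cohort, fused)
        assert len(table) == 1 and summary["n_slices"] == 1

    def test_include_degenerate_counts_all_slices(self):
        cohort = self._cohort()
        fused = {(s.patient_id, s.slice_id): s.ground_truth for s in cohort.slices}
        table, summary = evaluate_cohort(cohort, fused, include_degenerate=True)
        assert len(table) == 2 and summary["iou"] == pytest.approx(1.0)

    def test_missing_mask_raises_completeness_error(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="missing a mask"):
            evaluate_cohort(cohort, {}, method="m")
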