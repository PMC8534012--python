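"""Confusion counting, undefined-value handling, pooled mean F1,
consensus labels — including the naive per-pixel oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entireaxon.core import LabelMask, SegClass
from entireaxon.evaluation import (
    ConfusionCounts,
    consensus_label,
    count_confusion,
    evaluate_images,
    pooled_mean_f1,
    recall_precision,
)


def oracle_counts(pred, ref, valid=None):
    """Naive double-loop TP/FP/FN per class."""
    tp = np.zeros(4, int)
    fp = np.zeros(4, int)
    fn = np.zeros(4, int)
    h, w = ref.shape
    for y in range(h):
        for x in range(w):
            if valid is not None and not valid[y, x]:
                continue
            p, r = pred[y, x], ref[y, x]
            for c in range(4):
                if p == c and r == c:
                    tp[c] += 1
                elif p == c and r != c:
                    fp[c] += 1
                elif p != c and r == c:
                    fn[c] += 1
    return tp, fp, fn


class TestCountConfusion:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        m = LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8))
        c = count_confusion(m, m)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)
        assert c.tp.sum() == 64

    def test_worked_2x2_example(self):
        ref = LabelMask(np.full((2, 2), 1, dtype=np.uint8))
        pred = LabelMask(np.array([[1, 1], [1, 0]], dtype=np.uint8))
        c = count_confusion(pred, ref)
        assert c.tp[SegClass.AXON] == 3
        assert c.fn[SegClass.AXON] == 1
        assert c.fp[SegClass.AXON] == 0
        assert c.fp[SegClass.BACKGROUND] == 1

    def test_valid_mask_excludes_disagreement(self):
        ref = LabelMask(np.full((2, 2), 1, dtype=np.uint8))
        pred = LabelMask(np.array([[1, 1], [1, 0]], dtype=np.uint8))
        valid = np.array([[True, True], [True, False]])
        c = count_confusion(pred, ref, valid)
        assert np.all(c.fp == 0) and np.all(c.fn == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            count_confusion(
                LabelMask(np.zeros((2, 2), dtype=np.uint8)),
                LabelMask(np.zeros((3, 3), dtype=np.uint8)),
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), masked=st.booleans())
    def test_matches_naive_oracle_on_random_masks(self, seed, masked):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 4, (16, 16)).astype(np.uint8)
        ref = rng.integers(0, 4, (16, 16)).astype(np.uint8)
        valid = rng.random((16, 16)) > 0.3 if masked else None
        c = count_confusion(LabelMask(pred), LabelMask(ref), valid)
        tp, fp, fn = oracle_counts(pred, ref, valid)
        assert np.array_equal(c.tp, tp)
        assert np.array_equal(c.fp, fp)
        assert np.array_equal(c.fn, fn)
        # marginal identities
        for cls in range(4):
            n_ref = ((ref == cls) if valid is None else ((ref == cls) & valid)).sum()
            n_pred = ((pred == cls) if valid is None else ((pred == cls) & valid)).sum()
            assert c.tp[cls] + c.fn[cls] == n_ref
            assert c.tp[cls] + c.fp[cls] == n_pred


class TestRecallPrecision:
    def test_worked_recall(self):
        c = ConfusionCounts(tp=[8, 0, 0, 0], fp=[0, 0, 0, 0], fn=[2, 0, 0, 0])
        rec, prec = recall_precision(c)
        assert rec[0] == pytest.approx(0.8)

    def test_zero_denominators_are_nan_not_zero(self):
        c = ConfusionCounts(tp=[0, 0, 0, 0], fp=[0, 0, 0, 0], fn=[0, 5, 0, 0])
        rec, prec = recall_precision(c)
        assert np.isnan(prec[0])  # TP+FP == 0
        assert np.isnan(rec[0])   # TP+FN == 0
        assert rec[1] == 0.0      # defined: 0/(0+5)


class TestPooledMeanF1:
    def test_worked_example(self):
        c = ConfusionCounts(tp=[8, 0, 0, 0], fp=[2, 0, 0, 0], fn=[2, 0, 0, 0])
        assert pooled_mean_f1([c])[0] == pytest.approx(0.8)

    def test_pooled_differs_from_mean_of_f1s(self):
        c1 = ConfusionCounts(tp=[1, 0, 0, 0], fp=[0] * 4, fn=[0] * 4)
        c2 = ConfusionCounts(tp=[0] * 4, fp=[0] * 4, fn=[1, 0, 0, 0])
        # pooled: 2*1 / (2*1 + 0 + 1) = 2/3; per-image mean would be
        # (1 + undefined)/2 — pooling avoids the undefined value.
        assert pooled_mean_f1([c1, c2])[0] == pytest.approx(2 / 3)

    def test_absent_class_flagged_nan(self):
        c = ConfusionCounts(tp=[4, 0, 0, 0], fp=[0] * 4, fn=[0] * 4)
        f1 = pooled_mean_f1([c])
        assert np.isnan(f1[1:]).all()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_images=st.integers(1, 5))
    def test_equals_harmonic_mean_of_pooled_recall_precision(self, seed, n_images):
        rng = np.random.default_rng(seed)
        counts = [
            count_confusion(
                LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8)),
                LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8)),
            )
            for _ in range(n_images)
        ]
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        rec, prec = recall_precision(total)
        f1 = pooled_mean_f1(counts)
        for cls in range(4):
            if np.isnan(rec[cls]) or np.isnan(prec[cls]) or rec[cls] + prec[cls] == 0:
                continue
            assert f1[cls] == pytest.approx(
                2 * rec[cls] * prec[cls] / (rec[cls] + prec[cls])
            )


class TestConsensus:
    def test_identical_annotations_fully_valid(self):
        rng = np.random.default_rng(1)
        m = LabelMask(rng.integers(0, 4, (6, 6)).astype(np.uint8))
        cons = consensus_label(m, m)
        assert cons.valid.all()
        assert cons.valid_fraction == 1.0

    def test_valid_fraction_counts_disagreements(self):
        a = LabelMask(np.zeros((4, 4), dtype=np.uint8))
        b_grid = np.zeros((4, 4), dtype=np.uint8)
        b_grid[0, :3] = 1  # 3 of 16 differ
        cons = consensus_label(a, LabelMask(b_grid))
        assert cons.valid_fraction == pytest.approx(13 / 16)

    def test_invalid_pixels_do_not_affect_scoring(self):
        rng = np.random.default_rng(2)
        ref = LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8))
        other = LabelMask(ref.grid.copy())
        g = other.grid.copy()
        g[0, 0] = (g[0, 0] + 1) % 4
        cons = consensus_label(ref, LabelMask(g))
        pred1 = LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8))
        pred2_grid = pred1.grid.copy()
        pred2_grid[0, 0] = (pred2_grid[0, 0] + 2) % 4  # change on invalid px
        r1 = evaluate_images([pred1], [ref], [cons.valid])
        r2 = evaluate_images([LabelMask(pred2_grid)], [ref], [cons.valid])
        assert r1.equals(r2)


def test_report_layout():
    rng = np.random.default_rng(3)
    masks = [LabelMask(rng.integers(0, 4, (8, 8)).astype(np.uint8)) for _ in range(4)]
    df = evaluate_images(masks[:2], masks[2:])
    assert set(df.columns) >= {
        "class", "image", "TP", "FP", "FN", "recall", "precision", "pooled_mean_f1"
    }
    assert len(df) == 2 * 4
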