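"""Imbalance-aware segmentation scoring.

With ~96% background pixels, per-image recall/precision are frequently
undefined (no positives present, or none predicted), and averaging
per-image F1 scores is biased.  The headline statistic is therefore the
pooled (micro) mean F1: total TP, FP and FN are summed over all images
first, and F1 = 2 TP / (2 TP + FP + FN) is computed from the totals.
Undefined per-image values are reported as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import N_CLASSES, LabelMask, SegClass


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN pixel counts for one (or pooled) image(s)."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        for name in ("tp", "fp", "fn"):
            a = np.asarray(getattr(self, name), dtype=np.int64)
            if a.shape != (N_CLASSES,) or (a < 0).any():
                raise ValueError(f"{name} must be 4 non-negative counts")
            setattr(self, name, a)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class ConsensusLabel:
    """Per-pixel agreement between two annotators.

    ``agreed`` carries the common class on agreeing pixels and is only
    meaningful where ``valid`` is True; disagreeing pixels are excluded
    from any downstream scoring.
    """

    agreed: LabelMask
    valid: np.ndarray

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())


def count_confusion(
    pred: LabelMask, ref: LabelMask, valid: np.ndarray | None = None
) -> ConfusionCounts:
    """Per-class TP/FP/FN between a prediction and a reference mask.

    For each class c, the prediction and reference are binarized (1 = c,
    0 = all other classes) and pixel-wise TP/FP/FN are counted, over
    ``valid`` pixels only if a validity grid is given.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, ref {ref.shape}")
    p, r = pred.grid.astype(np.int64), ref.grid.astype(np.int64)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != p.shape:
            raise ValueError("validity grid shape must match the masks")
        p, r = p[valid], r[valid]
    joint = np.bincount(
        (r * N_CLASSES + p).ravel(), minlength=N_CLASSES * N_CLASSES
    ).reshape(N_CLASSES, N_CLASSES)  # joint[ref, pred]
    tp = np.diag(joint).copy()
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    return ConfusionCounts(tp, fp, fn)


def recall_precision(
    counts: ConfusionCounts,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class recall TP/(TP+FN) and precision TP/(TP+FP).

    Zero denominators yield NaN (undefined), never a silent zero.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(
            counts.tp + counts.fn > 0,
            counts.tp / np.maximum(counts.tp + counts.fn, 1),
            np.nan,
        )
        precision = np.where(
            counts.tp + counts.fp > 0,
            counts.tp / np.maximum(counts.tp + counts.fp, 1),
            np.nan,
        )
    return recall, precision


def pooled_mean_f1(counts_per_image: list[ConfusionCounts]) -> np.ndarray:
    """Pooled (micro) mean F1 per class from totals over all images.

    F1_c = 2 TP_total / (2 TP_total + FP_total + FN_total); a class with
    all-zero totals (absent everywhere and never predicted) is NaN.
    """
    if not counts_per_image:
        raise ValueError("at least one image is required")
    total = counts_per_image[0]
    for c in counts_per_image[1:]:
        total = total + c
    denom = 2 * total.tp + total.fp + total.fn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, 2 * total.tp / np.maximum(denom, 1), np.nan)


def consensus_label(a: LabelMask, b: LabelMask) -> ConsensusLabel:
    """Strict per-pixel consensus between two annotations."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    valid = a.grid == b.grid
    return ConsensusLabel(agreed=LabelMask(a.grid.copy()), valid=valid)


def evaluate_images(
    preds: list[LabelMask],
    refs: list[LabelMask],
    valids: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Score a set of images; returns a tidy per-class report.

    Columns: class, image, TP, FP, FN, recall, precision (NaN where
    undefined), pooled_mean_f1 (repeated per class across images).
    """
    if len(preds) != len(refs):
        raise ValueError("pred/ref image counts differ")
    valids = valids or [None] * len(preds)
    all_counts, rows = [], []
    for i, (p, r, v) in enumerate(zip(preds, refs, valids)):
        counts = count_confusion(p, r, v)
        all_counts.append(counts)
        rec, prec = recall_precision(counts)
        for c in SegClass:
            rows.append(
                {
                    "class": c.label,
                    "image": i,
                    "TP": counts.tp[c],
                    "FP": counts.fp[c],
                    "FN": counts.fn[c],
                    "recall": rec[c],
                    "precision": prec[c],
                }
            )
    f1 = pooled_mean_f1(all_counts)
    df = pd.DataFrame(rows)
    df["pooled_mean_f1"] = df["class"].map(
        {c.label: f1[c] for c in SegClass}
    )
    return df
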