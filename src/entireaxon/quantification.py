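"""Time-course readouts of axonal degeneration from segmentation videos.

Pixel counts of the three foreground classes (axon, swelling, fragment)
are summed per time point — across all videos of a condition when
grouped — and normalized to the total foreground area at baseline:

    normalized_area(t, c) = raw(t, c) / (axon(t0) + swelling(t0)
                                         + fragment(t0)) * 100

so the baseline areas sum to exactly 100% and later values may exceed
100% (axon growth).  The cumulative AUC readout is

    AUC = sum_i (v(t_i) + v(t_{i+1})) * (t_{i+1} - t_i)

evaluated verbatim on the normalized series; note this is twice the
composite trapezoid integral (``trapezoid=True`` halves it).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FOREGROUND_CLASSES, SegClass, SegmentationVideo

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassAreaSeries:
    """Per-time-point class pixel areas; ``normalized`` in percent of the
    baseline foreground area (None until :func:`normalize_series`)."""

    times: np.ndarray          # hours, length T
    raw: np.ndarray            # (T, 3) int counts: axon, swelling, fragment
    normalized: np.ndarray | None = None

    def __post_init__(self):
        if self.raw.shape != (len(self.times), len(FOREGROUND_CLASSES)):
            raise ValueError("raw series must be (T, 3)")
        if (self.raw < 0).any():
            raise ValueError("raw counts must be non-negative")

    def column(self, cls: SegClass, normalized: bool = True) -> np.ndarray:
        j = FOREGROUND_CLASSES.index(cls)
        if normalized:
            if self.normalized is None:
                raise ValueError("series not normalized yet")
            return self.normalized[:, j]
        return self.raw[:, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, cls in enumerate(FOREGROUND_CLASSES):
            for i, t in enumerate(self.times):
                rows.append(
                    {
                        "t_hours": float(t),
                        "class": cls.label,
                        "raw_px": int(self.raw[i, j]),
                        "normalized_pct": (
                            float(self.normalized[i, j])
                            if self.normalized is not None
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def class_area_series(
    video: SegmentationVideo | list[SegmentationVideo],
) -> ClassAreaSeries:
    """Raw per-time-point class pixel sums; a list of videos (one
    experimental condition) is summed pixel-wise per time point."""
    videos = video if isinstance(video, list) else [video]
    if not videos:
        raise ValueError("at least one video is required")
    T = videos[0].n_frames
    if any(v.n_frames != T for v in videos):
        raise ValueError("grouped videos must share the frame count")
    raw = np.zeros((T, len(FOREGROUND_CLASSES)), dtype=np.int64)
    for v in videos:
        arr = v.as_array()
        for j, cls in enumerate(FOREGROUND_CLASSES):
            raw[:, j] += (arr == int(cls)).sum(axis=(1, 2))
    return ClassAreaSeries(times=videos[0].times_hours, raw=raw)


def normalize_series(s: ClassAreaSeries) -> ClassAreaSeries:
    """Normalize to percent of total foreground area at baseline.

    The denominator is fixed at the first time point for all t.
    """
    baseline = int(s.raw[0].sum())
    if baseline == 0:
        raise ValueError(
            "no foreground pixels at baseline; exclude this unit from "
            "quantification (inclusion requires axons at the first frame)"
        )
    return ClassAreaSeries(
        times=s.times, raw=s.raw, normalized=s.raw / baseline * 100.0
    )


def auc(
    s: ClassAreaSeries,
    cls: SegClass,
    normalized: bool = True,
    trapezoid: bool = False,
) -> float:
    """Cumulative area under a class time course.

    Evaluates ``sum((v_i + v_{i+1}) * (t_{i+1} - t_i))`` — twice the
    trapezoid rule; pass ``trapezoid=True`` for the conventional value.
    """
    if len(s.times) < 2:
        raise ValueError("AUC needs at least 2 time points")
    v = s.column(cls, normalized=normalized)
    dt = np.diff(s.times)
    total = float(np.sum((v[:-1] + v[1:]) * dt))
    return total / 2.0 if trapezoid else total


def fragmentation_mask(video: SegmentationVideo) -> np.ndarray:
    """Boolean grid of pixels that degenerated during the recording.

    A pixel qualifies iff it was axon or swelling at some frame t and
    background or fragment at some later frame t' > t; pixels that only
    ever appear as fragment (no preceding axon/swelling state) are
    excluded.  Restricts pattern attribution to degenerated regions.
    """
    if video.n_frames < 2:
        raise ValueError("fragmentation mask needs >= 2 frames")
    arr = video.as_array()
    was_axon_or_swelling = np.maximum.accumulate(
        (arr == int(SegClass.AXON)) | (arr == int(SegClass.AXONAL_SWELLING)),
        axis=0,
    )
    gone = (arr == int(SegClass.BACKGROUND)) | (
        arr == int(SegClass.AXONAL_FRAGMENT)
    )
    return (gone[1:] & was_axon_or_swelling[:-1]).any(axis=0)


def pattern_percentage(
    pattern_pixels: dict[str, np.ndarray], fmask: np.ndarray
) -> dict[str, float]:
    """Percent of fragmentation-mask pixels attributed to each pattern.

    Patterns may overlap (a pixel can carry several patterns), so the
    percentages need not sum to 100.  An empty fragmentation mask yields
    NaN for every pattern, with a warning.
    """
    fmask = np.asarray(fmask, dtype=bool)
    denom = int(fmask.sum())
    if denom == 0:
        warnings.warn("empty fragmentation mask; pattern percentages undefined")
        return {name: float("nan") for name in pattern_pixels}
    out = {}
    for name, grid in pattern_pixels.items():
        grid = np.asarray(grid, dtype=bool)
        if grid.shape != fmask.shape:
            raise ValueError(f"pattern grid {name!r} shape mismatch")
        out[name] = float((grid & fmask).sum() / denom * 100.0)
    return out
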