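"""Raw-recording preprocessing: 8-bit conversion and stack alignment.

16-bit recordings are rescaled linearly from the per-stack global
[min, max] to [0, 255] (per-stack, not per-frame, so inter-frame
intensity relations are preserved).  Stage drift is removed by integer
translation-only registration against the first frame via phase
correlation; rotation is not estimated, and sub-pixel shifts are not
interpolated.  Borders exposed by the shifts are cropped away so the
output contains no padding artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .core import TimeLapseStack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentResult:
    """Per-frame integer (row, col) drift relative to frame 0 and the
    common valid region after correction."""

    shifts: list[tuple[int, int]]
    crop_box: tuple[int, int, int, int]  # top, left, height, width


def to_8bit(stack: TimeLapseStack) -> TimeLapseStack:
    """Convert a 16-bit stack to 8-bit by global linear rescaling.

    Values are mapped from [global min, global max] to [0, 255] and
    rounded half-up.  8-bit input passes through unchanged; a constant
    stack maps to all zeros with a warning.
    """
    if stack.bit_depth == 8:
        return stack
    arr = stack.as_array().astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        logger.warning("constant-valued stack; 8-bit output is all zeros")
        frames = [np.zeros(f.shape, dtype=np.uint8) for f in stack.frames]
    else:
        scaled = np.floor((arr - lo) / (hi - lo) * 255.0 + 0.5)
        frames = [f.astype(np.uint8) for f in scaled]
    return TimeLapseStack(
        frames, stack.t0_hours, stack.dt_hours, bit_depth=8
    )


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift content by (dy, dx) without wrapping; exposed borders are 0."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def align_stack(
    stack: TimeLapseStack, max_shift: int = 25
) -> tuple[TimeLapseStack, AlignmentResult]:
    """Register every frame to frame 0 by integer translation.

    ``shifts[i]`` is the estimated drift of frame i relative to frame 0
    (the correction applied is its negation).  A drift estimate larger
    than ``max_shift`` in either axis is distrusted: the frame is kept
    unshifted and a warning logged.  All frames are cropped to the
    common valid region.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    ref = stack.frames[0].astype(np.float64)
    shifts: list[tuple[int, int]] = [(0, 0)]
    for i, frame in enumerate(stack.frames[1:], start=1):
        if max_shift == 0:
            shifts.append((0, 0))
            continue
        est, _, _ = phase_cross_correlation(
            ref, frame.astype(np.float64), upsample_factor=1
        )
        # phase correlation returns the correction; drift is its negation
        dy, dx = int(round(-est[0])), int(round(-est[1]))
        if abs(dy) > max_shift or abs(dx) > max_shift:
            logger.warning(
                "frame %d drift estimate (%d, %d) exceeds max_shift=%d; "
                "frame kept unshifted", i, dy, dx, max_shift,
            )
            dy, dx = 0, 0
        shifts.append((dy, dx))

    h, w = stack.shape
    corrections = [(-dy, -dx) for dy, dx in shifts]
    top = max(max(c[0] for c in corrections), 0)
    bottom = h + min(min(c[0] for c in corrections), 0)
    left = max(max(c[1] for c in corrections), 0)
    right = w + min(min(c[1] for c in corrections), 0)
    crop_box = (top, left, bottom - top, right - left)

    frames = []
    for frame, (cy, cx) in zip(stack.frames, corrections):
        moved = _translate(frame, cy, cx) if (cy or cx) else frame
        frames.append(moved[top:bottom, left:right].copy())
    aligned = TimeLapseStack(
        frames, stack.t0_hours, stack.dt_hours, stack.bit_depth
    )
    return aligned, AlignmentResult(shifts=shifts, crop_box=crop_box)
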