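"""Shared domain types, class taxonomy, and mask/stack I/O.

Conventions used throughout the package:

* coordinates are 0-based and row-major (``row = y``, ``col = x``);
* frame index 0 maps to ``t0_hours`` (default 1.5 h) and consecutive
  frames are ``dt_hours`` (default 0.5 h) apart;
* label masks store the raw class codes 0-3, never colorized values, so
  file round-trips are bit-exact.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

N_CLASSES = 4

#: default time axis: recordings start 1.5 h after treatment, one frame
#: every 30 min for 24 h.
DEFAULT_T0_HOURS = 1.5
DEFAULT_DT_HOURS = 0.5


class SegClass(enum.IntEnum):
    """The four segmentation classes, with fixed pixel codes."""

    BACKGROUND = 0
    AXON = 1
    AXONAL_SWELLING = 2
    AXONAL_FRAGMENT = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "SegClass":
        return cls[name.upper()]


#: classes quantified in time courses (background excluded)
FOREGROUND_CLASSES = (
    SegClass.AXON,
    SegClass.AXONAL_SWELLING,
    SegClass.AXONAL_FRAGMENT,
)


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel class grid; ground truth or predicted segmentation map."""

    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {g.shape}")
        if not np.issubdtype(g.dtype, np.integer):
            raise TypeError(f"mask grid must be integer, got dtype {g.dtype}")
        if g.size and (g.min() < 0 or g.max() >= N_CLASSES):
            bad = sorted(set(np.unique(g)) - set(range(N_CLASSES)))
            raise ValueError(f"mask contains invalid class codes {bad}")
        object.__setattr__(self, "grid", g.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def one_hot(self) -> np.ndarray:
        """(rows, cols, 4) one-hot float view Y(x, y, c) of the grid."""
        return np.eye(N_CLASSES, dtype=np.float64)[self.grid]

    def class_counts(self) -> np.ndarray:
        """Pixel count per class code, length 4."""
        return np.bincount(self.grid.ravel(), minlength=N_CLASSES)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelMask) and np.array_equal(self.grid, other.grid)


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class distribution P(x, y, c) over the 4 classes."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != N_CLASSES:
            raise ValueError(
                f"probability map must be (rows, cols, {N_CLASSES}), got {p.shape}"
            )
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"per-pixel probabilities must sum to 1 (max deviation {worst:.2e})"
            )
        object.__setattr__(self, "probs", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]


def argmax_classes(p: ProbabilityMap) -> LabelMask:
    """Assign each pixel its most probable class.

    Ties are broken by the lowest class code (``np.argmax`` convention),
    which biases toward background — conservative detection.
    """
    return LabelMask(np.argmax(p.probs, axis=2).astype(np.uint8))


@dataclass
class TimeLapseStack:
    """An ordered stack of same-shape grayscale frames with a time axis."""

    frames: list[np.ndarray]
    t0_hours: float = DEFAULT_T0_HOURS
    dt_hours: float = DEFAULT_DT_HOURS
    bit_depth: int = 8

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a time-lapse stack requires >= 2 frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")
        if any(f.ndim != 2 for f in self.frames):
            raise ValueError("frames must be 2-D grayscale")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def times_hours(self) -> np.ndarray:
        return self.t0_hours + self.dt_hours * np.arange(self.n_frames)

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames)


@dataclass
class SegmentationVideo:
    """Per-frame label masks sharing the time axis of the source stack."""

    masks: list[LabelMask]
    t0_hours: float = DEFAULT_T0_HOURS
    dt_hours: float = DEFAULT_DT_HOURS

    def __post_init__(self):
        if not self.masks:
            raise ValueError("segmentation video requires >= 1 mask")
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError(f"all masks must share one shape, got {shapes}")

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    @property
    def times_hours(self) -> np.ndarray:
        return self.t0_hours + self.dt_hours * np.arange(self.n_frames)

    def as_array(self) -> np.ndarray:
        """(T, rows, cols) uint8 array of class codes."""
        return np.stack([m.grid for m in self.masks])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        t0_hours: float = DEFAULT_T0_HOURS,
        dt_hours: float = DEFAULT_DT_HOURS,
    ) -> "SegmentationVideo":
        return cls([LabelMask(a) for a in np.asarray(arr)], t0_hours, dt_hours)


# ---------------------------------------------------------------------------
# I/O


def _read_time_axis_sidecar(path: Path) -> dict:
    """Optional JSON sidecar <stem>.json with t0_hours / dt_hours."""
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return {
            k: float(meta[k]) for k in ("t0_hours", "dt_hours") if k in meta
        }
    return {}


def read_stack(
    path: str | Path,
    t0_hours: float | None = None,
    dt_hours: float | None = None,
) -> TimeLapseStack:
    """Read a time-lapse stack from a multi-page TIFF or an image directory.

    A directory is read as numbered single-page images in lexical order.
    The time axis comes from explicit arguments, a JSON sidecar
    (``<stem>.json`` with ``t0_hours`` / ``dt_hours``), or the defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack path does not exist: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FileNotFoundError(f"no image files in directory {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3:
            frames = list(arr)
        else:
            raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")

    if len(frames) < 2:
        raise ValueError(f"{path}: >= 2 frames required, found {len(frames)}")

    dt = frames[0].dtype
    if dt == np.uint8:
        bit_depth = 8
    elif dt == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported bit depth / dtype {dt} (need uint8 or uint16)")

    meta = _read_time_axis_sidecar(path)
    kwargs = {
        "t0_hours": t0_hours if t0_hours is not None else meta.get("t0_hours", DEFAULT_T0_HOURS),
        "dt_hours": dt_hours if dt_hours is not None else meta.get("dt_hours", DEFAULT_DT_HOURS),
    }
    return TimeLapseStack(frames=frames, bit_depth=bit_depth, **kwargs)


def write_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF plus a JSON time-axis sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.as_array())
    path.with_suffix(".json").write_text(
        json.dumps({"t0_hours": stack.t0_hours, "dt_hours": stack.dt_hours})
    )


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as a single-channel 8-bit image with raw codes 0-3."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.grid)
    else:
        iio.imwrite(path, mask.grid)


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask path does not exist: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(iio.imread(path))
    return LabelMask(arr.astype(np.uint8))


def write_mask_video(video: SegmentationVideo, path: str | Path) -> None:
    """Write a mask video as a multi-page 8-bit TIFF with raw codes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, video.as_array())
    path.with_suffix(".json").write_text(
        json.dumps({"t0_hours": video.t0_hours, "dt_hours": video.dt_hours})
    )


def read_mask_video(
    path: str | Path,
    t0_hours: float | None = None,
    dt_hours: float | None = None,
) -> SegmentationVideo:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask video path does not exist: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    meta = _read_time_axis_sidecar(path)
    return SegmentationVideo.from_array(
        arr.astype(np.uint8),
        t0_hours=t0_hours if t0_hours is not None else meta.get("t0_hours", DEFAULT_T0_HOURS),
        dt_hours=dt_hours if dt_hours is not None else meta.get("dt_hours", DEFAULT_DT_HOURS),
    )
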