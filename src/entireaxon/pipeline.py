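"""End-to-end orchestration: preprocess -> segment -> quantify -> patterns.

A :class:`RunConfig` fully determines a run; every run writes a manifest
(config + package version + seeds + a config hash) next to its outputs
so results can be reproduced byte-for-byte in deterministic mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    FOREGROUND_CLASSES,
    SegmentationVideo,
    TimeLapseStack,
    read_stack,
    write_mask_video,
    write_stack,
)
from .preprocess import align_stack, to_8bit
from .quantification import (
    auc,
    class_area_series,
    fragmentation_mask,
    normalize_series,
    pattern_percentage,
)
from .segmentation import SegEnsemble, SegmenterConfig, segment_video, train_segmenter
from .synthdata import make_pattern_dataset, make_segmentation_fixtures
from .temporal_patterns import (
    PATTERN_NAMES,
    RNNConfig,
    sliding_window_patterns,
    train_rnn,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run."""

    input_stack: str | None = None           # raw recording (TIFF)
    out_dir: str = "entireaxon_run"
    max_shift: int = 25
    seg_model_dir: str | None = None         # load a trained ensemble ...
    train_segmenter: bool = False            # ... or train one on synthetic data
    seg_config: SegmenterConfig = field(default_factory=SegmenterConfig.desk)
    n_train_fixtures: int = 30
    rnn_config: RNNConfig = field(default_factory=RNNConfig.desk)
    n_pattern_samples: int = 10              # per pattern, for RNN training
    pattern_window: int = 32
    pattern_stride: int | None = None
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "seg_config" in d and isinstance(d["seg_config"], dict):
            sc = d["seg_config"]
            if "rotation_range_deg" in sc:
                sc["rotation_range_deg"] = tuple(sc["rotation_range_deg"])
            d["seg_config"] = SegmenterConfig(**sc)
        if "rnn_config" in d and isinstance(d["rnn_config"], dict):
            d["rnn_config"] = RNNConfig(**d["rnn_config"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_full(
    cfg: RunConfig, stack: TimeLapseStack | None = None
) -> dict:
    """Execute the whole pipeline and write all outputs under ``out_dir``.

    ``stack`` may be passed directly (e.g. a simulated recording);
    otherwise it is read from ``cfg.input_stack``.  Returns the manifest
    dict (also written to ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input -----------------------------------------------------------
    if stack is None:
        if not cfg.input_stack:
            raise StageError("input", "no input stack given")
        try:
            stack = read_stack(cfg.input_stack)
        except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
            raise StageError("input", str(e)) from e

    # --- preprocess ------------------------------------------------------
    try:
        stack8 = to_8bit(stack)
        aligned, alignment = align_stack(stack8, cfg.max_shift)
        write_stack(aligned, out / "aligned.tif")
    except StageError:
        raise
    except Exception as e:
        raise StageError("preprocess", str(e)) from e

    # --- segmentation ----------------------------------------------------
    try:
        if cfg.seg_model_dir:
            ensemble = SegEnsemble.load(cfg.seg_model_dir)
        elif cfg.train_segmenter:
            seg_cfg = cfg.seg_config
            fixtures = make_segmentation_fixtures(
                cfg.n_train_fixtures, seed=cfg.seed
            )
            ensemble, _ = train_segmenter(fixtures, seg_cfg)
            ensemble.save(out / "seg_model")
        else:
            raise FileNotFoundError(
                "no segmentation model: set seg_model_dir or enable "
                "train_segmenter"
            )
        video = segment_video(ensemble, aligned)
        write_mask_video(video, out / "masks.tif")
    except StageError:
        raise
    except Exception as e:
        raise StageError("segmentation", str(e)) from e

    # --- quantification --------------------------------------------------
    try:
        series = normalize_series(class_area_series(video))
        series.to_frame().to_csv(out / "series.csv", index=False)
        aucs = {
            cls.label: auc(series, cls) for cls in FOREGROUND_CLASSES
        }
        pd.DataFrame(
            [{"class": k, "auc": v} for k, v in aucs.items()]
        ).to_csv(out / "auc.csv", index=False)
        fmask = fragmentation_mask(video)
    except StageError:
        raise
    except Exception as e:
        raise StageError("quantification", str(e)) from e

    # --- patterns --------------------------------------------------------
    try:
        samples = make_pattern_dataset(
            cfg.n_pattern_samples, T=min(video.n_frames, 24),
            seed=cfg.seed + 1,
        )
        rnn, _ = train_rnn(samples, cfg.rnn_config)
        grids = sliding_window_patterns(
            video, rnn, fmask,
            window=cfg.pattern_window, stride=cfg.pattern_stride,
        )
        pct = pattern_percentage(grids, fmask) if fmask.any() else {
            name: float("nan") for name in PATTERN_NAMES
        }
        pd.DataFrame(
            [{"pattern": k, "percent_of_fragmentation_mask": v}
             for k, v in pct.items()]
        ).to_csv(out / "patterns.csv", index=False)
    except StageError:
        raise
    except Exception as e:
        raise StageError("patterns", str(e)) from e

    manifest = {
        "version": __version__,
        "config": json.loads(cfg.to_json()),
        "config_hash": cfg.config_hash(),
        "alignment_shifts": [list(s) for s in alignment.shifts],
        "crop_box": list(alignment.crop_box),
        "n_frames": video.n_frames,
        "fragmentation_mask_px": int(fmask.sum()),
        "auc": aucs,
        "pattern_percent": pct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
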