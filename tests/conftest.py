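"""Shared fixtures.

The two trained models (segmentation ensemble, pattern-classifier
cross-validation) are expensive, so they are session-scoped and shared
between the behavioural tests and the end-to-end checks.
"""

import numpy as np
import pytest

from entireaxon.core import LabelMask, SegmentationVideo
from entireaxon.segmentation import SegmenterConfig, train_segmenter
from entireaxon.synthdata import make_pattern_dataset, make_segmentation_fixtures
from entireaxon.temporal_patterns import RNNConfig, tenfold_cv


def random_video(rng: np.random.Generator, T: int, h: int, w: int) -> SegmentationVideo:
    return SegmentationVideo.from_array(
        rng.integers(0, 4, size=(T, h, w)).astype(np.uint8)
    )


def random_mask(rng: np.random.Generator, h: int, w: int) -> LabelMask:
    return LabelMask(rng.integers(0, 4, size=(h, w)).astype(np.uint8))


@pytest.fixture(scope="session")
def seg_fixture_set():
    """36 static synthetic scenes: 30 train + 6 held out."""
    return make_segmentation_fixtures(36, seed=11)


@pytest.fixture(scope="session")
def trained_segmenter(seg_fixture_set):
    """Desk-scale 2-member ensemble trained on 30 synthetic scenes."""
    ensemble, curves = train_segmenter(
        seg_fixture_set[:30], SegmenterConfig.desk(seed=0)
    )
    return ensemble, curves, seg_fixture_set[30:]


@pytest.fixture(scope="session")
def pattern_samples():
    """48 single-pattern histogram sequences (12 per pattern)."""
    return make_pattern_dataset(12, T=24, seed=1)


@pytest.fixture(scope="session")
def pattern_cv(pattern_samples):
    """Pooled 10-fold cross-validation report of the pattern classifier."""
    return tenfold_cv(pattern_samples, RNNConfig.desk(seed=0))
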