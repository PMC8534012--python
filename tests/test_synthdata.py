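"""The simulator: determinism, scripted dynamics, imbalance profile,
image/mask co-location, annotator perturbation, and the separability of
the four degeneration signatures."""

import numpy as np
import pytest
from scipy import ndimage

from entireaxon.core import SegClass
from entireaxon.synthdata import (
    PATTERNS,
    AxonSceneSpec,
    DegenerationScript,
    evaluator_perturb,
    make_pattern_dataset,
    make_segmentation_fixtures,
    simulate_timelapse,
)
from entireaxon.evaluation import consensus_label


SCENE = AxonSceneSpec(shape=(64, 64), n_axons=1, seed=3)


class TestSimulateTimelapse:
    def test_bit_identical_for_same_seed(self):
        s1, v1 = simulate_timelapse(SCENE, DegenerationScript(), T=8)
        s2, v2 = simulate_timelapse(SCENE, DegenerationScript(), T=8)
        assert np.array_equal(s1.as_array(), s2.as_array())
        assert np.array_equal(v1.as_array(), v2.as_array())

    def test_growth_pattern_axon_non_decreasing(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="none"), T=12
        )
        counts = (v.as_array() == int(SegClass.AXON)).sum(axis=(1, 2))
        assert (np.diff(counts) >= 0).all()

    def test_granular_fragments_only_after_onset(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="granular", onset_frame=5), T=12
        )
        frag = (v.as_array() == int(SegClass.AXONAL_FRAGMENT)).sum(axis=(1, 2))
        assert (frag[:5] == 0).all()
        assert frag[5:].max() > 0

    def test_retraction_extent_strictly_decreases(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="retraction", onset_frame=3), T=14
        )
        axon_px = (v.as_array() == int(SegClass.AXON)).sum(axis=(1, 2))
        shrinking = axon_px[3:]
        shrinking = shrinking[shrinking > 0]
        assert (np.diff(shrinking) < 0).all()

    def test_swelling_radius_grows_after_onset(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="swelling", onset_frame=2), T=9
        )
        sw = (v.as_array() == int(SegClass.AXONAL_SWELLING)).sum(axis=(1, 2))
        assert sw[6] > sw[1] > 0

    def test_transport_swellings_move_then_halt(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="transport", onset_frame=6), T=10
        )
        arr = v.as_array()
        centroids = []
        for t in range(8):
            pts = np.argwhere(arr[t] == int(SegClass.AXONAL_SWELLING))
            centroids.append(pts.mean(axis=0))
        moving = np.linalg.norm(centroids[4] - centroids[1])
        halted = np.linalg.norm(centroids[7] - centroids[6])
        assert moving > 2.0
        assert halted < 1.0

    def test_onset_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            simulate_timelapse(
                SCENE, DegenerationScript(pattern="granular", onset_frame=30),
                T=10,
            )

    def test_image_intensity_colocates_with_classes(self):
        stack, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="swelling", onset_frame=4), T=6
        )
        img = stack.frames[3].astype(float)
        g = v.masks[3].grid
        bg = img[g == 0].mean()
        ax = img[g == int(SegClass.AXON)].mean()
        sw = img[g == int(SegClass.AXONAL_SWELLING)].mean()
        assert sw > ax > bg

    def test_fragments_disconnected_from_axon(self):
        _, v = simulate_timelapse(
            SCENE, DegenerationScript(pattern="granular", onset_frame=3), T=8
        )
        g = v.masks[5].grid
        frag = g == int(SegClass.AXONAL_FRAGMENT)
        if frag.any():
            labeled, n = ndimage.label(frag)
            assert n > 1  # separated granules, not one connected blob


class TestSegmentationFixtures:
    def test_imbalance_profile_and_background_dominance(self):
        pairs = make_segmentation_fixtures(5, seed=0)
        for img, mask in pairs:
            frac = mask.class_counts() / mask.grid.size
            assert frac[0] > 0.9
            spec = AxonSceneSpec()
            for cls in (SegClass.AXON, SegClass.AXONAL_SWELLING,
                        SegClass.AXONAL_FRAGMENT):
                assert 0.5 * spec.imbalance[cls] <= frac[cls] <= 1.5 * spec.imbalance[cls]

    def test_seeded_determinism(self):
        a = make_segmentation_fixtures(3, seed=5)
        b = make_segmentation_fixtures(3, seed=5)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia, ib)
            assert ma == mb

    def test_all_classes_covered_across_set(self):
        pairs = make_segmentation_fixtures(5, seed=1)
        seen = set()
        for _, mask in pairs:
            seen |= set(np.unique(mask.grid).tolist())
        assert seen == {0, 1, 2, 3}


class TestPatternDataset:
    def test_counts_and_shapes(self):
        samples = make_pattern_dataset(3, T=10, seed=0)
        assert len(samples) == 12
        for s in samples:
            assert s["histograms"].shape == (9, 16)
            assert s["labels"].sum() == 1

    def test_histograms_normalized(self):
        samples = make_pattern_dataset(2, T=8, seed=2)
        for s in samples:
            assert np.allclose(s["histograms"].sum(axis=1), 1.0, atol=1e-9)

    def test_granular_has_axon_to_fragment_mass(self):
        samples = make_pattern_dataset(4, T=16, seed=3)
        bin_af = 1 * 4 + 3  # axon -> fragment
        gran = [s for s in samples if s["patterns"] == ("granular",)]
        assert all(s["histograms"][:, bin_af].sum() > 0 for s in gran)

    def test_mixed_samples_are_multilabel(self):
        samples = make_pattern_dataset(1, T=12, seed=4, include_mixed=3)
        mixed = [s for s in samples if len(s["patterns"]) == 2]
        assert len(mixed) == 3
        for s in mixed:
            assert s["labels"].sum() == 2

    def test_signatures_separable_by_centroid_classifier(self):
        """The four scripts must be distinguishable from histograms alone
        (otherwise the sequence-classification task is ill-posed)."""
        train = make_pattern_dataset(15, T=24, seed=5)
        test = make_pattern_dataset(10, T=24, seed=6)
        feats = lambda s: s["histograms"].sum(axis=0)
        cents = {
            p: np.mean([feats(s) for s in train if s["patterns"] == (p,)], axis=0)
            for p in PATTERNS
        }
        correct = sum(
            min(cents, key=lambda p: np.linalg.norm(feats(s) - cents[p]))
            == s["patterns"][0]
            for s in test
        )
        assert correct / len(test) > 0.25  # better than chance


class TestEvaluatorPerturb:
    def _thin_mask(self):
        g = np.zeros((40, 40), dtype=np.uint8)
        g[10:12, 2:38] = 1
        g[20, 5:30] = 1
        from entireaxon.core import LabelMask

        return LabelMask(g)

    def test_rate_zero_identity(self):
        m = self._thin_mask()
        assert evaluator_perturb(m, 0.0, seed=0) == m

    def test_flip_count_tracks_rate(self):
        m = self._thin_mask()
        n_boundary = int(
            (m.grid > 0).sum()
        )  # thin structures: all foreground is boundary
        changed = (evaluator_perturb(m, 0.3, seed=1).grid != m.grid).sum()
        # binomial(n, 0.3) within 4 sd
        sd = np.sqrt(n_boundary * 0.3 * 0.7)
        assert abs(changed - 0.3 * n_boundary) < 4 * sd

    def test_consensus_with_perturbed_not_fully_valid(self):
        m = self._thin_mask()
        cons = consensus_label(m, evaluator_perturb(m, 0.2, seed=2))
        assert cons.valid_fraction < 1.0
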