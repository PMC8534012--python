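"""Transition histograms (with per-pixel oracle), erosion augmentation,
attention decoder contracts, fold construction, and t-SNE embedding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entireaxon.core import LabelMask, SegmentationVideo
from entireaxon.temporal_patterns import (
    N_BINS,
    N_PATTERNS,
    AttentionRNN,
    RNNConfig,
    TransitionHistogramSeries,
    decode_patterns,
    embed_representations,
    erode_augment,
    erode_mask_video,
    make_folds,
    train_rnn,
    transition_histograms,
)


def video_of(*frames):
    return SegmentationVideo.from_array(np.array(frames, dtype=np.uint8))


def oracle_histograms(arr):
    """Per-pixel double-loop transition counts."""
    T, h, w = arr.shape
    H0 = np.zeros((T - 1, 16), dtype=np.int64)
    for t in range(T - 1):
        for y in range(h):
            for x in range(w):
                H0[t, arr[t, y, x] * 4 + arr[t + 1, y, x]] += 1
    return H0


class TestTransitionHistograms:
    def test_worked_2x2_example(self):
        v = video_of([[0, 1], [1, 2]], [[0, 1], [3, 2]])
        hs = transition_histograms(v)
        bi = TransitionHistogramSeries.bin_index
        expected = np.zeros(16, int)
        expected[bi(0, 0)] = 1
        expected[bi(1, 1)] = 1
        expected[bi(1, 3)] = 1
        expected[bi(2, 2)] = 1
        assert np.array_equal(hs.H0[0], expected)
        assert hs.H[0][expected > 0].tolist() == [0.25] * 4

    def test_identical_frames_mass_on_diagonal(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 4, (6, 6)).astype(np.uint8)
        hs = transition_histograms(video_of(frame, frame))
        off_diag = [k for k in range(16) if k // 4 != k % 4]
        assert hs.H0[0, off_diag].sum() == 0

    def test_t_frames_give_t_minus_1_histograms(self):
        rng = np.random.default_rng(1)
        v = SegmentationVideo.from_array(
            rng.integers(0, 4, (5, 4, 4)).astype(np.uint8)
        )
        hs = transition_histograms(v)
        assert hs.H0.shape == (4, N_BINS)
        assert N_BINS == 16

    def test_window_restriction(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 4, (3, 8, 8)).astype(np.uint8)
        hs = transition_histograms(
            SegmentationVideo.from_array(arr), window=(2, 3, 4, 4)
        )
        sub = arr[:, 2:6, 3:7]
        assert np.array_equal(hs.H0, oracle_histograms(sub))
        with pytest.raises(ValueError, match="outside"):
            transition_histograms(SegmentationVideo.from_array(arr),
                                  window=(6, 6, 4, 4))

    def test_single_frame_rejected(self):
        v = video_of([[0]])
        with pytest.raises(ValueError, match="2 frames"):
            transition_histograms(v)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 6))
        arr = rng.integers(0, 4, (T, 8, 8)).astype(np.uint8)
        hs = transition_histograms(SegmentationVideo.from_array(arr))
        assert np.array_equal(hs.H0, oracle_histograms(arr))
        # normalization: every non-empty histogram sums to 1
        sums = hs.H.sum(axis=1)
        assert np.allclose(sums[~hs.empty], 1.0, atol=1e-9)
        # raw counts sum to the pixel count per frame pair
        assert (hs.H0.sum(axis=1) == 64).all()


class TestErosionAugmentation:
    def test_six_entries_per_sample(self):
        rng = np.random.default_rng(3)
        videos = [
            SegmentationVideo.from_array(
                rng.integers(0, 4, (2, 8, 8)).astype(np.uint8)
            )
            for _ in range(5)
        ]
        out = erode_augment(videos)
        assert len(out) == 30

    def test_all_background_unchanged(self):
        v = SegmentationVideo.from_array(np.zeros((2, 8, 8), dtype=np.uint8))
        out = erode_mask_video(v, 3)
        assert np.array_equal(out.as_array(), v.as_array())

    def test_size3_cross_removes_1px_line(self):
        grid = np.zeros((9, 9), dtype=np.uint8)
        grid[4, 1:8] = 1  # 1-px-wide axon line
        v = SegmentationVideo([LabelMask(grid)] * 2)
        out = erode_mask_video(v, 3)
        assert out.as_array().sum() == 0

    def test_wide_structure_survives_partially(self):
        grid = np.zeros((12, 12), dtype=np.uint8)
        grid[3:9, 3:9] = 2
        v = SegmentationVideo([LabelMask(grid)] * 2)
        out = erode_mask_video(v, 3)
        arr = out.as_array()
        assert arr.sum() > 0
        assert set(np.unique(arr)) <= {0, 2}


class TestDecoderContracts:
    @pytest.fixture
    def model(self):
        return AttentionRNN(max_steps=7, cfg=RNNConfig.desk(seed=0))

    def test_attention_is_probability_distribution(self, model):
        rng = np.random.default_rng(4)
        seq = rng.dirichlet(np.ones(16), size=7)
        _, trace, _ = decode_patterns(model, seq)
        for alpha in trace:
            assert alpha.min() >= 0
            assert alpha.sum() == pytest.approx(1.0, abs=1e-6)

    def test_five_decoding_iterations_for_four_patterns(self, model):
        rng = np.random.default_rng(5)
        _, trace, _ = decode_patterns(model, rng.dirichlet(np.ones(16), size=7))
        assert len(trace) == N_PATTERNS + 1 == 5

    def test_zero_weights_give_half_scores(self, model):
        for p in model.parameters():
            p.data[...] = 0.0
        rng = np.random.default_rng(6)
        y, _, _ = decode_patterns(model, rng.dirichlet(np.ones(16), size=7))
        assert np.allclose(y, 0.5)

    def test_scores_strictly_inside_unit_interval(self, model):
        rng = np.random.default_rng(7)
        y, _, _ = decode_patterns(model, rng.dirichlet(np.ones(16), size=5))
        assert np.all(y > 0) and np.all(y < 1)
        assert y.shape == (N_PATTERNS,)

    def test_encode_deterministic_and_order_sensitive(self, model):
        rng = np.random.default_rng(8)
        seq = rng.dirichlet(np.ones(16), size=7)
        model.eval()
        X, _ = model._pad_batch([seq])
        v1 = model.encode(X, np.random.default_rng(0)).data
        v2 = model.encode(X, np.random.default_rng(99)).data
        assert np.array_equal(v1, v2)  # dropout off at inference
        assert v1.shape == (1, 7, model.cfg.hidden)
        Xp, _ = model._pad_batch([seq[::-1]])
        assert not np.allclose(v1, model.encode(Xp, np.random.default_rng(0)).data)

    def test_padding_steps_get_no_attention(self, model):
        rng = np.random.default_rng(9)
        seq = rng.dirichlet(np.ones(16), size=4)  # shorter than max_steps=7
        _, trace, _ = decode_patterns(model, seq)
        for alpha in trace:
            assert alpha[4:].max() < 1e-8

    def test_overlong_sequence_rejected(self, model):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="exceeds model capacity"):
            model.forward([rng.dirichlet(np.ones(16), size=20)])


class TestTraining:
    def _toy_samples(self, n=12, T=6, seed=0):
        """Linearly separable toy task: pattern c puts mass in bin c."""
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(n):
            c = i % 4
            H = rng.dirichlet(np.ones(16), size=T)
            H[:, c] += 3.0
            H /= H.sum(axis=1, keepdims=True)
            labels = np.zeros(4)
            labels[c] = 1.0
            samples.append({"histograms": H, "labels": labels})
        return samples

    def test_loss_decreases_by_half(self):
        cfg = RNNConfig.desk(seed=0)
        cfg.epochs = 30
        _, curve = train_rnn(self._toy_samples(), cfg)
        assert curve[-1] < 0.5 * curve[0]

    def test_seeded_reproducibility(self):
        cfg = RNNConfig.desk(seed=1)
        cfg.epochs = 3
        m1, c1 = train_rnn(self._toy_samples(), cfg)
        m2, c2 = train_rnn(self._toy_samples(), cfg)
        assert c1 == c2
        for k, v in m1.state_dict().items():
            assert np.array_equal(v, m2.state_dict()[k])

    def test_unlabelled_samples_allowed(self):
        samples = self._toy_samples(8)
        samples[0]["labels"] = np.zeros(4)
        cfg = RNNConfig.desk(seed=0)
        cfg.epochs = 2
        train_rnn(samples, cfg)  # must not raise

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_rnn([], RNNConfig.desk())


class TestFolds:
    def test_partition_identity(self):
        rng = np.random.default_rng(11)
        labels = np.eye(4)[rng.integers(0, 4, 40)]
        folds = make_folds(labels, 10, seed=0)
        allidx = np.concatenate(folds)
        assert len(allidx) == 40
        assert len(np.unique(allidx)) == 40  # disjoint and covering

    def test_every_fold_has_every_class(self):
        labels = np.eye(4)[np.arange(40) % 4]
        folds = make_folds(labels, 10, seed=0)
        for f in folds:
            assert (labels[f].sum(axis=0) >= 1).all()

    def test_relaxation_warns_when_class_scarce(self):
        labels = np.zeros((12, 4))
        labels[:, 0] = 1
        labels[0, 1] = 1  # class 1 has a single sample
        with pytest.warns(UserWarning, match="relaxed"):
            make_folds(labels, 10, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            make_folds(np.eye(4), 10)


class TestEmbedding:
    def test_cardinality_and_determinism(self):
        rng = np.random.default_rng(12)
        zs = rng.normal(size=(20, 16))
        e1 = embed_representations(zs, seed=0)
        e2 = embed_representations(zs, seed=0)
        assert e1.shape == (20, 2)
        assert np.array_equal(e1, e2)

    def test_separated_groups_stay_separated(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(15, 16))
        b = rng.normal(size=(15, 16)) + 12.0
        emb = embed_representations(np.vstack([a, b]), seed=0)
        ea, eb = emb[:15], emb[15:]
        intra = np.mean([
            np.linalg.norm(g - g.mean(0), axis=1).mean() for g in (ea, eb)
        ])
        inter = np.linalg.norm(ea.mean(0) - eb.mean(0))
        assert inter > intra
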