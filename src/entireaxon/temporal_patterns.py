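"""Classification of morphological degeneration patterns from mask videos.

A segmentation video is reduced to a sequence of 16-bin class-transition
histograms: for consecutive frames t and t+1 each pixel contributes one
count to the bin of its class pair (c1, c2) in {0..3}^2, and each
histogram is normalized to sum to 1.  An attention encoder-decoder GRU
maps the histogram sequence to four independent sigmoid scores, one per
degeneration pattern (granular, retraction, swelling, transport).

The decoder is iterative: with C = 4 patterns it runs C + 1 steps, each
step attending over the encoded time axis, updating a gated recurrent
state, and adding a correction to the running output vector; the final
output is squashed by the sigmoid.  The final decoder state doubles as a
fixed-length sample representation used for embedding/clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import N_CLASSES, LabelMask, SegmentationVideo
from .nn import (
    Dropout,
    GRUStack,
    Module,
    Tensor,
    concatenate,
    glorot_init,
    make_optimizer,
)
from .nn.tensor import bce_with_logits

logger = logging.getLogger(__name__)

N_PATTERNS = 4
PATTERN_NAMES = ("granular", "retraction", "swelling", "transport")
N_BINS = N_CLASSES * N_CLASSES  # 16 class pairs


# ---------------------------------------------------------------------------
# transition histograms


@dataclass(frozen=True)
class TransitionHistogramSeries:
    """T-1 transition histograms for a T-frame mask video.

    ``H0[t, k]`` counts pixels with class pair ``(k // 4, k % 4)`` between
    frames t and t+1; ``H`` is each row of ``H0`` normalized to sum to 1
    (rows with zero total are flagged in ``empty`` and left at zero).
    """

    H0: np.ndarray
    H: np.ndarray
    n_frames: int
    empty: np.ndarray

    def __post_init__(self):
        if self.H0.shape != (self.n_frames - 1, N_BINS):
            raise ValueError(
                f"expected {self.n_frames - 1} x {N_BINS} histograms, "
                f"got {self.H0.shape}"
            )

    @staticmethod
    def bin_index(c1: int, c2: int) -> int:
        return c1 * N_CLASSES + c2


def transition_histograms(
    video: SegmentationVideo,
    window: tuple[int, int, int, int] | None = None,
) -> TransitionHistogramSeries:
    """Compute the 16-bin class-transition histogram series of a video.

    ``window`` is an optional (top, left, height, width) region; counts
    are restricted to it.
    """
    if video.n_frames < 2:
        raise ValueError("at least 2 frames are needed for transitions")
    arr = video.as_array().astype(np.int64)
    if window is not None:
        top, left, h, w = window
        if (
            top < 0 or left < 0
            or top + h > arr.shape[1] or left + w > arr.shape[2]
        ):
            raise ValueError(f"window {window} outside video bounds {arr.shape[1:]}")
        arr = arr[:, top : top + h, left : left + w]
    pair_codes = arr[:-1] * N_CLASSES + arr[1:]  # (T-1, h, w)
    T1 = pair_codes.shape[0]
    H0 = np.zeros((T1, N_BINS), dtype=np.int64)
    for t in range(T1):
        H0[t] = np.bincount(pair_codes[t].ravel(), minlength=N_BINS)
    totals = H0.sum(axis=1, keepdims=True)
    empty = totals[:, 0] == 0
    H = np.divide(
        H0, np.where(totals == 0, 1, totals), dtype=np.float64
    )
    return TransitionHistogramSeries(
        H0=H0, H=H, n_frames=video.n_frames, empty=empty
    )


# ---------------------------------------------------------------------------
# erosion augmentation


def _cross_kernel(size: int) -> np.ndarray:
    k = np.zeros((size, size), dtype=bool)
    k[size // 2, :] = True
    k[:, size // 2] = True
    return k


def erode_mask_video(video: SegmentationVideo, size: int) -> SegmentationVideo:
    """Erode the non-background region of every frame with a cross kernel.

    Pixels eroded away revert to background; surviving pixels keep their
    class.  Emulates thinner axons for augmentation.
    """
    kernel = _cross_kernel(size)
    out = []
    for m in video.masks:
        fg = m.grid > 0
        keep = ndimage.binary_erosion(fg, structure=kernel, border_value=0)
        out.append(LabelMask(np.where(keep, m.grid, 0).astype(np.uint8)))
    return SegmentationVideo(out, video.t0_hours, video.dt_hours)


def erode_augment(
    mask_videos: Sequence[SegmentationVideo],
    sizes: tuple[int, ...] = (3, 5, 7),
) -> list[SegmentationVideo]:
    """Expand each video into 6 entries: 3 eroded versions + 3 unchanged
    copies, keeping a 50% chance of drawing the original during training."""
    out: list[SegmentationVideo] = []
    for v in mask_videos:
        for s in sizes:
            out.append(erode_mask_video(v, s))
        out.extend([v] * len(sizes))
    return out


# ---------------------------------------------------------------------------
# the attention encoder-decoder RNN


@dataclass
class RNNConfig:
    """Training/architecture configuration for the pattern classifier.

    Reference-scale defaults: hidden dimension 256, 3 GRU layers each in
    encoder and decoder, dropout 0.9, LAMB optimizer, lr 0.01 decayed by
    10x every 15 epochs, weight decay 1e-4, batch 128, 60 epochs.
    ``desk()`` returns a configuration small enough to train in seconds
    on one CPU for tests and demos.
    """

    hidden: int = 256
    n_layers: int = 3
    dropout: float = 0.9
    epochs: int = 60
    batch_size: int = 128
    lr: float = 0.01
    lr_decay_every: int = 15
    lr_decay_factor: float = 10.0
    weight_decay: float = 1e-4
    optimizer: str = "lamb"
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "RNNConfig":
        return cls(
            hidden=48,
            n_layers=2,
            dropout=0.1,
            epochs=60,
            batch_size=16,
            lr=0.02,
            lr_decay_every=30,
            seed=seed,
        )


class AttentionRNN(Module):
    """Encoder-decoder GRU with additive output and time attention.

    encode:  V = f_enc(H),  one hidden row per histogram step.
    decode:  o_0 = 0, s_0 = 0; for i = 1..C+1:
                 alpha_i = softmax(W_att [s_{i-1}, ReLU(W_in o_{i-1})])
                 c_i     = V^T alpha_i
                 z_i, s_i = GRU(c_i, s_{i-1})
                 o_i     = o_{i-1} + W_out z_i
             y = sigmoid(o_{C+1})
    """

    def __init__(self, max_steps: int, cfg: RNNConfig):
        self.cfg = cfg
        self.max_steps = max_steps  # maximum number of histogram steps (T-1)
        d = cfg.hidden
        rng = np.random.default_rng(cfg.seed)
        self.encoder = GRUStack(N_BINS, d, cfg.n_layers, rng, cfg.dropout)
        self.decoder = GRUStack(d, d, cfg.n_layers, rng, cfg.dropout)
        self.w_in = Tensor(glorot_init(rng, N_PATTERNS, d), requires_grad=True)
        self.w_att = Tensor(glorot_init(rng, 2 * d, max_steps), requires_grad=True)
        self.w_out = Tensor(glorot_init(rng, d, N_PATTERNS), requires_grad=True)
        self.drop = Dropout(cfg.dropout)

    # -- batching ----------------------------------------------------------

    def _pad_batch(self, seqs: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Pad (T_i, 16) sequences to (B, max_steps, 16) + padding mask."""
        B = len(seqs)
        X = np.zeros((B, self.max_steps, N_BINS))
        pad = np.ones((B, self.max_steps), dtype=bool)
        for i, s in enumerate(seqs):
            t = s.shape[0]
            if t > self.max_steps:
                raise ValueError(
                    f"sequence of {t} steps exceeds model capacity "
                    f"{self.max_steps}; rebuild the model with a larger "
                    "max_steps"
                )
            X[i, :t] = s
            pad[i, :t] = False
        return X, pad

    def encode(
        self, X: np.ndarray, rng: np.random.Generator
    ) -> Tensor:
        """Hidden representation V, shape (B, max_steps, d)."""
        B = X.shape[0]
        states = self.encoder.init_state(B)
        rows = []
        for t in range(self.max_steps):
            top, states = self.encoder.step(Tensor(X[:, t]), states, rng)
            rows.append(top.reshape(B, 1, self.cfg.hidden))
        return concatenate(rows, axis=1)

    def decode(
        self, V: Tensor, pad: np.ndarray, rng: np.random.Generator
    ) -> tuple[Tensor, list[np.ndarray], Tensor]:
        """Iterative decoding; returns (logits o_{C+1}, attention trace, z)."""
        B = V.shape[0]
        d = self.cfg.hidden
        o = Tensor(np.zeros((B, N_PATTERNS)))
        states = self.decoder.init_state(B)
        neg = np.where(pad, -1e9, 0.0)
        attn_trace: list[np.ndarray] = []
        z = None
        for _ in range(N_PATTERNS + 1):
            s_top = states[-1]
            query = concatenate([s_top, (o @ self.w_in).relu()], axis=1)
            logits = query @ self.w_att + Tensor(neg)
            alpha = logits.softmax(axis=1)
            attn_trace.append(alpha.data.copy())
            context = (alpha.reshape(B, 1, self.max_steps) @ V).reshape(B, d)
            z, states = self.decoder.step(context, states, rng)
            o = o + z @ self.w_out
        return o, attn_trace, z

    def forward(
        self,
        seqs: Sequence[np.ndarray],
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[np.ndarray], Tensor]:
        rng = rng or np.random.default_rng(0)
        X, pad = self._pad_batch(seqs)
        V = self.encode(X, rng)
        return self.decode(V, pad, rng)

    def predict(
        self, seqs: Sequence[np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pattern scores y in (0,1)^4 and sample representations z."""
        self.eval()
        logits, _, z = self.forward(seqs)
        from .nn.tensor import _sigmoid

        return _sigmoid(logits.data), z.data.copy()


def decode_patterns(
    model: AttentionRNN, histograms: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Score one histogram sequence; returns (y, attention trace, z)."""
    model.eval()
    logits, trace, z = model.forward([np.asarray(histograms)])
    from .nn.tensor import _sigmoid

    return _sigmoid(logits.data[0]), [a[0] for a in trace], z.data[0]


# ---------------------------------------------------------------------------
# training


def train_rnn(
    samples: Sequence[dict],
    cfg: RNNConfig | None = None,
    max_steps: int | None = None,
) -> tuple[AttentionRNN, list[float]]:
    """Train the pattern classifier on labelled histogram sequences.

    ``samples`` are dicts with ``histograms`` ((T-1, 16) arrays) and
    ``labels`` ((4,) multi-hot vectors; all-zero labels are allowed).
    Returns the trained model and the per-epoch mean loss curve.
    """
    if not samples:
        raise ValueError("empty training set")
    cfg = cfg or RNNConfig.desk()
    max_steps = max_steps or max(s["histograms"].shape[0] for s in samples)
    model = AttentionRNN(max_steps, cfg)
    opt = make_optimizer(
        cfg.optimizer, model.parameters(), cfg.lr, cfg.weight_decay
    )
    rng = np.random.default_rng(cfg.seed + 1)
    X = [np.asarray(s["histograms"], dtype=np.float64) for s in samples]
    Y = np.stack([np.asarray(s["labels"], dtype=np.float64) for s in samples])
    n = len(X)
    curve: list[float] = []
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr / (
            cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)
        )
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, _, _ = model.forward([X[i] for i in idx], rng)
            loss = bce_with_logits(logits, Y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        curve.append(float(np.mean(losses)))
        logger.debug("epoch %d mean loss %.4f", epoch, curve[-1])
    return model, curve


# ---------------------------------------------------------------------------
# sliding-window inference


def sliding_window_patterns(
    video: SegmentationVideo,
    model: AttentionRNN,
    fmask: np.ndarray,
    window: int = 32,
    stride: int | None = None,
    threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Pixel-wise pattern attribution by tiled window classification.

    Each ``window`` x ``window`` tile is converted to transition
    histograms and scored; every pattern whose sigmoid score exceeds
    ``threshold`` marks the tile's fragmentation-mask pixels.  Returns one
    boolean grid per pattern name.
    """
    stride = stride or window
    h, w = video.shape
    fmask = np.asarray(fmask, dtype=bool)
    if fmask.shape != (h, w):
        raise ValueError("fragmentation mask shape must match the video")
    grids = {name: np.zeros((h, w), dtype=bool) for name in PATTERN_NAMES}
    if not fmask.any():
        return grids
    if h < window or w < window:
        warnings.warn(
            f"video {h}x{w} smaller than the {window}px window; "
            "evaluating one padded window"
        )
        arr = video.as_array()
        padded = np.zeros((arr.shape[0], max(h, window), max(w, window)), dtype=arr.dtype)
        padded[:, :h, :w] = arr
        video = SegmentationVideo.from_array(padded, video.t0_hours, video.dt_hours)
        h2, w2 = video.shape
    else:
        h2, w2 = h, w
    tops = list(range(0, h2 - window + 1, stride))
    lefts = list(range(0, w2 - window + 1, stride))
    if tops[-1] + window < h2:
        tops.append(h2 - window)
    if lefts[-1] + window < w2:
        lefts.append(w2 - window)
    seqs, boxes = [], []
    for top in tops:
        for left in lefts:
            box = (top, left, window, window)
            if not fmask[top : top + window, left : left + window][: h - top, : w - left].any():
                continue
            seqs.append(transition_histograms(video, window=box).H)
            boxes.append(box)
    if not seqs:
        return grids
    scores, _ = model.predict(seqs)
    for (top, left, wh, ww), y in zip(boxes, scores):
        tile = fmask[top : top + wh, left : left + ww]
        for ci, name in enumerate(PATTERN_NAMES):
            if y[ci] > threshold:
                grids[name][top : top + wh, left : left + ww] |= tile
    return grids


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Partition sample indices into folds, each containing at least one
    sample of every pattern class when feasible (relaxed with a warning
    otherwise)."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    per_class = [np.flatnonzero(labels[:, c] > 0) for c in range(labels.shape[1])]
    if any(len(ix) < n_folds for ix in per_class):
        warnings.warn(
            "some pattern has fewer samples than folds; the one-per-fold "
            "constraint is relaxed"
        )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    assigned: set[int] = set()
    # round-robin per class so each fold sees each class when possible
    for ix in per_class:
        ix = [i for i in rng.permutation(ix) if i not in assigned]
        for k, i in enumerate(ix):
            folds[k % n_folds].append(i)
            assigned.add(i)
    rest = [i for i in rng.permutation(n) if i not in assigned]
    sizes = np.array([len(f) for f in folds])
    for i in rest:
        k = int(np.argmin(sizes))
        folds[k].append(i)
        sizes[k] += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def tenfold_cv(
    samples: Sequence[dict],
    cfg: RNNConfig | None = None,
    n_folds: int = 10,
    threshold: float = 0.5,
) -> dict:
    """10-fold cross-validation of the pattern classifier.

    Trains one model per fold on the complement, scores the held-out
    fold, pools all test predictions, and reports per-pattern pooled
    precision, recall and F1 (from total TP/FP/FN, as in the imbalance-
    aware segmentation evaluation).
    """
    cfg = cfg or RNNConfig.desk()
    Y = np.stack([np.asarray(s["labels"]) for s in samples])
    folds = make_folds(Y, n_folds=n_folds, seed=cfg.seed)
    max_steps = max(s["histograms"].shape[0] for s in samples)
    n = len(samples)
    preds = np.zeros((n, N_PATTERNS))
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_cfg = RNNConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        model, _ = train_rnn(
            [samples[i] for i in train_idx], fold_cfg, max_steps=max_steps
        )
        scores, _ = model.predict(
            [samples[i]["histograms"] for i in test_idx]
        )
        preds[test_idx] = scores
    called = preds > threshold
    report = {"folds": folds, "scores": preds, "per_pattern": {}}
    for ci, name in enumerate(PATTERN_NAMES):
        tp = int(np.sum(called[:, ci] & (Y[:, ci] > 0)))
        fp = int(np.sum(called[:, ci] & (Y[:, ci] == 0)))
        fn = int(np.sum(~called[:, ci] & (Y[:, ci] > 0)))
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
        report["per_pattern"][name] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": prec, "recall": rec, "f1": f1,
        }
    return report


# ---------------------------------------------------------------------------
# representation embedding


def embed_representations(
    zs: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding of per-sample decoder representations."""
    from sklearn.manifold import TSNE

    zs = np.asarray(zs)
    if zs.ndim != 2 or len(zs) < 2:
        raise ValueError("need a (n >= 2, d) array of representations")
    max_perp = (len(zs) - 1) / 3.0
    if perplexity > max_perp:
        logger.info(
            "perplexity %.1f too large for %d samples; reduced to %.1f",
            perplexity, len(zs), max_perp,
        )
        perplexity = max(1.0, max_perp)
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(zs)
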