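"""Four-class semantic segmentation of phase-contrast axon images.

A U-shaped fully-convolutional network (encoder-decoder with skip
connections, per-pixel 4-class softmax) is trained with the per-pixel
cross-entropy loss

    Loss(P, Y) = - sum_{x,y,c} Y(x,y,c) log P(x,y,c)

under random-crop / horizontal-flip / rotation augmentation, and applied
as a mean ensemble: the per-pixel class distributions of the members are
averaged.  Encoder depth is configurable — ``small`` (two resolution
levels, trains in minutes on one CPU) or ``reference`` (deep ResNet-scale
encoder) — the per-pixel softmax contract is identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    N_CLASSES,
    LabelMask,
    ProbabilityMap,
    SegmentationVideo,
    TimeLapseStack,
    argmax_classes,
)
from .nn import Conv2d, Module, Tensor, concatenate, make_optimizer
from .nn.tensor import maxpool2, upsample2

logger = logging.getLogger(__name__)

#: grayscale image-net standardization constants (mean of the RGB values,
#: on the 0-255 scale), selectable instead of train-set statistics
IMAGENET_MEAN = 0.449 * 255.0
IMAGENET_STD = 0.226 * 255.0

ENCODER_CHANNELS = {
    "small": (12, 24),
    "reference": (64, 128, 256, 512),
}


@dataclass
class SegmenterConfig:
    """Training configuration.

    Reference-scale defaults: 8-model ensemble, 180 epochs, batch 4,
    Adam at lr 1e-3 decayed by 10x every 60 epochs, 512-px crops, deep
    encoder.  ``desk()`` is the CPU-scale preset used by the tests.
    """

    n_models: int = 8
    epochs: int = 180
    batch_size: int = 4
    lr0: float = 1e-3
    lr_decay_every: int = 60
    lr_decay_factor: float = 10.0
    crop_size: int = 512
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0)
    encoder_depth: str = "reference"
    normalization: str = "trainset"  # or "imagenet"
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1 or self.epochs < 1:
            raise ValueError("n_models and epochs must be >= 1")
        if self.encoder_depth not in ENCODER_CHANNELS:
            raise ValueError(f"unknown encoder depth {self.encoder_depth!r}")

    @classmethod
    def desk(cls, seed: int = 0) -> "SegmenterConfig":
        return cls(
            n_models=2,
            epochs=10,
            batch_size=4,
            lr0=2e-3,
            lr_decay_every=6,
            crop_size=96,
            encoder_depth="small",
            seed=seed,
        )


# ---------------------------------------------------------------------------
# loss (public metric form, on probability maps)


def cross_entropy_loss(p: ProbabilityMap, y: LabelMask) -> float:
    """Per-pixel cross-entropy summed over the image, log clipped at 1e-12."""
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    logp = np.log(np.clip(p.probs, 1e-12, None))
    return float(-(y.one_hot() * logp).sum())


# ---------------------------------------------------------------------------
# augmentation


def augment_sample(
    image: np.ndarray,
    mask: LabelMask,
    rng: np.random.Generator,
    crop_size: int,
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0),
) -> tuple[np.ndarray, LabelMask]:
    """Random crop + horizontal flip + rotation, identically on both.

    The mask is interpolated nearest-neighbour so codes stay in {0..3};
    rotation fills exposed corners with 0 (background) in both arrays.
    """
    h, w = image.shape
    if h < crop_size or w < crop_size:
        raise ValueError(
            f"image {h}x{w} smaller than crop size {crop_size}"
        )
    top = int(rng.integers(0, h - crop_size + 1))
    left = int(rng.integers(0, w - crop_size + 1))
    img = image[top : top + crop_size, left : left + crop_size].astype(np.float64)
    m = mask.grid[top : top + crop_size, left : left + crop_size]
    if rng.random() < 0.5:
        img = img[:, ::-1]
        m = m[:, ::-1]
    angle = float(rng.uniform(*rotation_range_deg))
    img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
    m = ndimage.rotate(m, angle, reshape=False, order=0, mode="constant", cval=0)
    return img, LabelMask(np.ascontiguousarray(m).astype(np.uint8))


def sample_rotation_angle(
    rng: np.random.Generator,
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0),
) -> float:
    """The augmentation angle sampler (uniform over the configured range)."""
    return float(rng.uniform(*rotation_range_deg))


# ---------------------------------------------------------------------------
# the network


class UNet(Module):
    """Encoder-decoder FCN with skip connections and 4-class output."""

    def __init__(self, channels: tuple[int, ...], rng: np.random.Generator,
                 in_ch: int = 1, n_classes: int = N_CLASSES):
        self.channels = tuple(channels)
        L = len(channels)
        self.enc = []
        prev = in_ch
        for c in channels:
            self.enc.append([Conv2d(prev, c, 3, rng), Conv2d(c, c, 3, rng)])
            prev = c
        self.dec = []
        for i in range(L - 2, -1, -1):
            cin = channels[i + 1] + channels[i]
            self.dec.append([Conv2d(cin, channels[i], 3, rng)])
        self.head = Conv2d(channels[0], n_classes, 1, rng)
        # flatten block lists so Module.parameters() finds them
        self._blocks = [c for blk in self.enc + self.dec for c in blk] + [self.head]

    def parameters(self):
        params = []
        for blk in self._blocks:
            params.extend(blk.parameters())
        return params

    def modules(self):
        yield self
        for blk in self._blocks:
            yield from blk.modules()

    def state_dict(self):
        out = {}
        for i, blk in enumerate(self._blocks):
            for k, v in blk.state_dict().items():
                out[f"b{i}.{k}"] = v
        return out

    def load_state_dict(self, state):
        for i, blk in enumerate(self._blocks):
            blk.load_state_dict(
                {k.split(".", 1)[1]: v for k, v in state.items()
                 if k.startswith(f"b{i}.")}
            )

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) standardized input -> (N, 4, H, W) logits.

        H and W must be divisible by 2**(levels-1).
        """
        skips = []
        h = x
        for i, (c1, c2) in enumerate(self.enc):
            h = c2(c1(h).relu()).relu()
            if i < len(self.enc) - 1:
                skips.append(h)
                h = maxpool2(h)
        for (c,), skip in zip(self.dec, reversed(skips)):
            h = concatenate([upsample2(h), skip], axis=1)
            h = c(h).relu()
        return self.head(h)


def _pad_to_multiple(arr: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode="edge")
    return arr, (h, w)


# ---------------------------------------------------------------------------
# the ensemble


@dataclass
class SegEnsemble:
    """A mean ensemble of trained segmenters plus input normalization."""

    members: list[UNet]
    mean: float
    std: float
    config: SegmenterConfig

    def predict(self, frame: np.ndarray) -> ProbabilityMap:
        return predict_ensemble(self, frame)

    def save(self, path: str | Path) -> None:
        """Write weights, config and a seed manifest to a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            np.savez(path / f"member_{i}.npz", **m.state_dict())
        manifest = {
            "config": {**asdict(self.config)},
            "mean": self.mean,
            "std": self.std,
            "n_members": len(self.members),
            "member_seeds": [
                self.config.seed + i for i in range(len(self.members))
            ],
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegEnsemble":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        cfg_d = manifest["config"]
        cfg_d["rotation_range_deg"] = tuple(cfg_d["rotation_range_deg"])
        cfg = SegmenterConfig(**cfg_d)
        members = []
        channels = ENCODER_CHANNELS[cfg.encoder_depth]
        for i in range(manifest["n_members"]):
            net = UNet(channels, np.random.default_rng(cfg.seed + i))
            with np.load(path / f"member_{i}.npz") as z:
                net.load_state_dict(dict(z))
            members.append(net)
        return cls(members, manifest["mean"], manifest["std"], cfg)


def train_segmenter(
    train_set: list[tuple[np.ndarray, LabelMask]],
    cfg: SegmenterConfig,
) -> tuple[SegEnsemble, list[list[float]]]:
    """Train an ensemble of ``cfg.n_models`` networks from distinct seeds.

    Returns the ensemble and each member's per-epoch mean loss curve
    (mean per-pixel cross-entropy).  A non-finite loss aborts training.
    """
    if not train_set:
        raise ValueError("empty training set")
    for img, m in train_set:
        if img.shape != m.shape:
            raise ValueError("image/mask shape mismatch in training set")

    if cfg.normalization == "imagenet":
        mean, std = IMAGENET_MEAN, IMAGENET_STD
    else:
        pix = np.concatenate([img.ravel() for img, _ in train_set]).astype(np.float64)
        mean, std = float(pix.mean()), float(pix.std() + 1e-8)

    channels = ENCODER_CHANNELS[cfg.encoder_depth]
    mult = 2 ** (len(channels) - 1)
    if cfg.crop_size % mult:
        raise ValueError(f"crop size must be divisible by {mult}")
    members, curves = [], []
    eye = np.eye(N_CLASSES)
    for mi in range(cfg.n_models):
        rng = np.random.default_rng(cfg.seed + mi)
        net = UNet(channels, rng)
        opt = make_optimizer("adam", net.parameters(), cfg.lr0)
        curve = []
        for epoch in range(cfg.epochs):
            opt.lr = cfg.lr0 / (
                cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)
            )
            order = rng.permutation(len(train_set))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                imgs, masks = [], []
                for i in idx:
                    img, m = augment_sample(
                        train_set[i][0], train_set[i][1], rng,
                        cfg.crop_size, cfg.rotation_range_deg,
                    )
                    imgs.append((img - mean) / std)
                    masks.append(m.grid)
                x = Tensor(np.stack(imgs)[:, None])
                onehot = eye[np.stack(masks)].transpose(0, 3, 1, 2)
                logits = net.forward(x)
                n_px = onehot.size // N_CLASSES
                loss = (
                    -(Tensor(onehot) * logits.log_softmax(axis=1)).sum()
                    * (1.0 / n_px)
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss (member {mi}, epoch {epoch})"
                    )
                net.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            curve.append(float(np.mean(losses)))
            logger.debug("member %d epoch %d loss %.4f", mi, epoch, curve[-1])
        members.append(net)
        curves.append(curve)
    return SegEnsemble(members, mean, std, cfg), curves


def predict_member(
    net: UNet, frame: np.ndarray, mean: float, std: float
) -> np.ndarray:
    """One member's (H, W, 4) per-pixel class distribution."""
    mult = 2 ** (len(net.channels) - 1)
    x, (h, w) = _pad_to_multiple((frame.astype(np.float64) - mean) / std, mult)
    logits = net.forward(Tensor(x[None, None]))
    probs = logits.softmax(axis=1).data[0, :, :h, :w]
    return probs.transpose(1, 2, 0)


def predict_ensemble(ensemble: SegEnsemble, frame: np.ndarray) -> ProbabilityMap:
    """Arithmetic mean of the members' per-pixel class distributions."""
    if not ensemble.members:
        raise ValueError("ensemble has no members")
    acc = None
    for net in ensemble.members:
        p = predict_member(net, frame, ensemble.mean, ensemble.std)
        acc = p if acc is None else acc + p
    return ProbabilityMap(acc / len(ensemble.members))


def segment_video(
    ensemble: SegEnsemble, stack: TimeLapseStack
) -> SegmentationVideo:
    """Per-frame argmax segmentation of a preprocessed 8-bit stack."""
    if stack.bit_depth != 8:
        raise ValueError("segment_video expects a preprocessed 8-bit stack")
    masks = [
        argmax_classes(predict_ensemble(ensemble, f)) for f in stack.frames
    ]
    return SegmentationVideo(masks, stack.t0_hours, stack.dt_hours)
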