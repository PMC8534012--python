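"""Seeded simulator of degenerating axons in phase-contrast-like recordings.

The generator draws curvilinear axons (smooth random-walk paths a few
pixels wide) on a dominant background, attaches blob-like swellings, and
scripts one of four morphological degeneration fates over the time axis:

* ``granular``   — the axon disintegrates in place into separated granules
  (fragment class) which then fade to background;
* ``retraction`` — the distal axon pulls back frame by frame, and the
  remaining stub finally fragments;
* ``swelling``   — swellings enlarge progressively, then the axon
  fragments;
* ``transport``  — constant-size swellings travel along the shaft, halt,
  and the axon fragments later;
* ``none``       — continued growth, no degeneration.

Masks are exact renderings of the scripted geometry; images are the masks
rendered with class-specific intensities, a dark phase-contrast-like halo
ring and Gaussian noise.  Every output is a pure function of the seed and
parameters.

The default static-scene class balance targets a strongly imbalanced
regime (~96% background, ~2.8% axon, ~0.6% swelling, ~0.2% fragment),
typical of sparse axonal cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_DT_HOURS,
    DEFAULT_T0_HOURS,
    LabelMask,
    SegClass,
    SegmentationVideo,
    TimeLapseStack,
)

#: class pixel fractions of the target imbalance regime
DEFAULT_IMBALANCE = {
    SegClass.BACKGROUND: 0.9642,
    SegClass.AXON: 0.0277,
    SegClass.AXONAL_SWELLING: 0.0058,
    SegClass.AXONAL_FRAGMENT: 0.0023,
}

Pattern = Literal["granular", "retraction", "swelling", "transport", "none"]
PATTERNS: tuple[str, ...] = ("granular", "retraction", "swelling", "transport")


@dataclass(frozen=True)
class AxonSceneSpec:
    """Geometry and photometry of a simulated scene."""

    shape: tuple[int, int] = (128, 128)
    n_axons: int = 2
    axon_width_px: float = 2.0
    swelling_radius_range: tuple[float, float] = (2.0, 3.2)
    background_level: float = 40.0
    axon_delta: float = 55.0
    swelling_delta: float = 85.0
    fragment_delta: float = 65.0
    noise_sd: float = 5.0
    halo_amplitude: float = 18.0
    imbalance: dict = field(default_factory=lambda: dict(DEFAULT_IMBALANCE))
    seed: int = 0

    def __post_init__(self):
        h, w = self.shape
        rmax = self.swelling_radius_range[1]
        if 2 * rmax >= min(h, w) or self.axon_width_px >= min(h, w):
            raise ValueError("geometric parameters exceed image bounds")


@dataclass(frozen=True)
class DegenerationScript:
    """Parametric description of one simulated axon's fate."""

    pattern: Pattern = "granular"
    onset_frame: int = 5
    retraction_speed_px: float = 4.0
    swelling_growth_px: float = 0.35
    transport_velocity_px: float = 3.0
    fragmentation_duration_frames: int = 6
    growth_px_per_frame: float = 1.5

    def __post_init__(self):
        if self.onset_frame < 0:
            raise ValueError("onset frame must be >= 0")
        for k in (
            "retraction_speed_px",
            "swelling_growth_px",
            "transport_velocity_px",
            "growth_px_per_frame",
        ):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")
        if self.fragmentation_duration_frames < 1:
            raise ValueError("fragmentation duration must be >= 1 frame")


# ---------------------------------------------------------------------------
# geometry helpers


def _axon_path(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_points: int,
    step: float = 1.0,
    margin: float = 4.0,
) -> np.ndarray:
    """Smooth random-walk polyline (n_points, 2) in (row, col) coordinates."""
    h, w = shape
    pos = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w / 3)]
    )
    heading = rng.uniform(-0.4, 0.4)  # roughly rightward
    pts = [pos.copy()]
    for _ in range(n_points - 1):
        heading += rng.normal(0.0, 0.15)
        # steer back toward the interior when close to a border
        target = np.array([h / 2, w / 2])
        to_center = target - pos
        dist_edge = min(pos[0], h - pos[0], pos[1], w - pos[1])
        if dist_edge < 3 * margin:
            center_heading = np.arctan2(to_center[0], to_center[1])
            heading = 0.7 * heading + 0.3 * center_heading
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pos[0] = np.clip(pos[0], margin / 2, h - margin / 2)
        pos[1] = np.clip(pos[1], margin / 2, w - margin / 2)
        pts.append(pos.copy())
    return np.array(pts)


def _paint_disks(
    canvas: np.ndarray, points: np.ndarray, radius: float, value: int
) -> None:
    """Set `canvas` to `value` inside disks of `radius` around `points`."""
    h, w = canvas.shape
    r = max(radius, 0.5)
    ri = int(np.ceil(r))
    yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    disk = yy**2 + xx**2 <= r**2
    for py, px in np.atleast_2d(points):
        cy, cx = int(round(py)), int(round(px))
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, h)
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        sub = disk[y0 - (cy - ri) : y1 - (cy - ri), x0 - (cx - ri) : x1 - (cx - ri)]
        canvas[y0:y1, x0:x1][sub] = value


def _arclength(path: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at(path: np.ndarray, s_arc: np.ndarray, s: float) -> np.ndarray:
    """Path point at arclength ``s`` (clamped)."""
    idx = int(np.searchsorted(s_arc, np.clip(s, 0.0, s_arc[-1])))
    return path[min(idx, len(path) - 1)]


# ---------------------------------------------------------------------------
# rendering


def render_image(
    mask: LabelMask, spec: AxonSceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render a mask into a noisy 8-bit phase-contrast-like frame.

    Foreground classes are brighter than background (swellings brightest),
    and a dark ring around foreground mimics the phase-contrast halo.
    """
    g = mask.grid
    delta = np.zeros(g.shape, dtype=np.float64)
    delta[g == SegClass.AXON] = spec.axon_delta
    delta[g == SegClass.AXONAL_SWELLING] = spec.swelling_delta
    delta[g == SegClass.AXONAL_FRAGMENT] = spec.fragment_delta
    fg = (g > 0).astype(np.float64)
    halo = np.clip(ndimage.gaussian_filter(fg, 2.0) - fg, 0.0, None)
    img = (
        spec.background_level
        + ndimage.gaussian_filter(delta, 0.6)
        - spec.halo_amplitude * halo
        + rng.normal(0.0, spec.noise_sd, size=g.shape)
    )
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# scripted degeneration of a single axon


class _AxonState:
    """Precomputed geometry for one axon plus its script."""

    def __init__(
        self,
        rng: np.random.Generator,
        spec: AxonSceneSpec,
        script: DegenerationScript,
        n_path_points: int = 140,
    ):
        self.spec = spec
        self.script = script
        self.path = _axon_path(rng, spec.shape, n_path_points)
        self.s_arc = _arclength(self.path)
        self.total_len = float(self.s_arc[-1])
        # granule layout used by the terminal fragmentation phase
        spacing = rng.uniform(4.0, 6.0)
        self.granule_s = np.arange(2.0, self.total_len, spacing)
        self.granule_r = rng.uniform(0.8, 1.4, size=len(self.granule_s))
        self.granule_fade = rng.integers(
            script.fragmentation_duration_frames,
            script.fragmentation_duration_frames * 3 + 1,
            size=len(self.granule_s),
        )
        p = script.pattern
        if p in ("swelling", "transport"):
            n_sw = int(rng.integers(2, 4))
            lo = 0.2 * self.total_len
            hi = 0.8 * self.total_len
            self.swelling_s0 = rng.uniform(lo, hi, size=n_sw)
            self.swelling_r0 = rng.uniform(*spec.swelling_radius_range, size=n_sw)
        else:
            self.swelling_s0 = np.zeros(0)
            self.swelling_r0 = np.zeros(0)

    # -- helpers ----------------------------------------------------------

    def _paint_axon(self, canvas: np.ndarray, s_max: float, s_min: float = 0.0):
        sel = (self.s_arc >= s_min) & (self.s_arc <= s_max)
        if sel.any():
            _paint_disks(
                canvas,
                self.path[sel],
                self.spec.axon_width_px / 2.0,
                int(SegClass.AXON),
            )

    def _paint_swellings(self, canvas, s_positions, radii):
        for s, r in zip(s_positions, radii):
            pt = _point_at(self.path, self.s_arc, s)
            _paint_disks(canvas, pt[None, :], r, int(SegClass.AXONAL_SWELLING))

    def _paint_granules(self, canvas, frames_since_frag: int, s_max=None):
        sel = self.granule_fade > frames_since_frag
        if s_max is not None:
            sel &= self.granule_s <= s_max
        for s, r in zip(self.granule_s[sel], self.granule_r[sel]):
            pt = _point_at(self.path, self.s_arc, s)
            _paint_disks(canvas, pt[None, :], r, int(SegClass.AXONAL_FRAGMENT))

    # -- per-frame mask ----------------------------------------------------

    def paint_frame(self, canvas: np.ndarray, t: int) -> None:
        sc = self.script
        p = sc.pattern
        if p == "none":
            base = 0.55 * self.total_len
            s_max = min(base + sc.growth_px_per_frame * t, self.total_len)
            self._paint_axon(canvas, s_max)
            return

        if p == "granular":
            if t < sc.onset_frame:
                self._paint_axon(canvas, self.total_len)
            else:
                self._paint_granules(canvas, t - sc.onset_frame)
            return

        if p == "retraction":
            # distal pullback at constant speed; stub fragments once short
            if t < sc.onset_frame:
                self._paint_axon(canvas, self.total_len)
                return
            s_max = self.total_len - sc.retraction_speed_px * (t - sc.onset_frame + 1)
            stub = 0.25 * self.total_len
            if s_max > stub:
                self._paint_axon(canvas, s_max)
            else:
                frag_t = int(
                    np.ceil((self.total_len - stub) / sc.retraction_speed_px)
                )
                self._paint_granules(
                    canvas, t - sc.onset_frame - frag_t + 1, s_max=stub
                )
            return

        if p == "swelling":
            grow_frames = 8
            frag_start = sc.onset_frame + grow_frames
            if t < frag_start:
                self._paint_axon(canvas, self.total_len)
                growth = sc.swelling_growth_px * max(t - sc.onset_frame + 1, 0)
                self._paint_swellings(
                    canvas, self.swelling_s0, self.swelling_r0 + growth
                )
            else:
                self._paint_granules(canvas, t - frag_start)
            return

        if p == "transport":
            # swellings travel until onset, then halt; fragmentation later
            halt_to_frag = 6
            frag_start = sc.onset_frame + halt_to_frag
            if t < frag_start:
                self._paint_axon(canvas, self.total_len)
                t_move = min(t, sc.onset_frame)
                s_pos = np.minimum(
                    self.swelling_s0 + sc.transport_velocity_px * t_move,
                    0.95 * self.total_len,
                )
                self._paint_swellings(canvas, s_pos, self.swelling_r0)
            else:
                self._paint_granules(canvas, t - frag_start)
            return

        raise ValueError(f"unknown pattern {p!r}")


# ---------------------------------------------------------------------------
# public generators


def simulate_timelapse(
    scene: AxonSceneSpec,
    script: DegenerationScript,
    T: int = 46,
) -> tuple[TimeLapseStack, SegmentationVideo]:
    """Simulate a paired (image stack, ground-truth mask video).

    The mask video follows the degeneration script exactly; the image
    stack is the rendered masks plus halo and noise.  Identical seeds
    yield bit-identical outputs.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if script.pattern != "none" and script.onset_frame >= T:
        raise ValueError("onset frame must fall inside the recording")
    rng = np.random.default_rng(scene.seed)
    axons = [
        _AxonState(rng, scene, script) for _ in range(max(scene.n_axons, 1))
    ]
    masks, frames = [], []
    for t in range(T):
        canvas = np.zeros(scene.shape, dtype=np.uint8)
        for ax in axons:
            ax.paint_frame(canvas, t)
        mask = LabelMask(canvas)
        masks.append(mask)
        frames.append(render_image(mask, scene, rng))
    stack = TimeLapseStack(
        frames, t0_hours=DEFAULT_T0_HOURS, dt_hours=DEFAULT_DT_HOURS, bit_depth=8
    )
    video = SegmentationVideo(
        masks, t0_hours=DEFAULT_T0_HOURS, dt_hours=DEFAULT_DT_HOURS
    )
    return stack, video


def _static_scene(
    rng: np.random.Generator, spec: AxonSceneSpec
) -> LabelMask:
    """One static frame whose class fractions track the imbalance profile."""
    h, w = spec.shape
    n_px = h * w
    target_axon = spec.imbalance[SegClass.AXON] * n_px
    target_sw = spec.imbalance[SegClass.AXONAL_SWELLING] * n_px
    target_fr = spec.imbalance[SegClass.AXONAL_FRAGMENT] * n_px

    canvas = np.zeros(spec.shape, dtype=np.uint8)
    # grow axon paths until the axon pixel budget is met
    per_axon = int(1.1 * target_axon / spec.axon_width_px / max(spec.n_axons, 1))
    for _ in range(max(spec.n_axons, 1)):
        path = _axon_path(rng, spec.shape, max(per_axon, 20))
        _paint_disks(canvas, path, spec.axon_width_px / 2.0, int(SegClass.AXON))

    # swellings on axon pixels
    ax_px = np.argwhere(canvas == SegClass.AXON)
    mean_sw_area = np.pi * (np.mean(spec.swelling_radius_range) ** 2)
    n_sw = max(int(round(target_sw / mean_sw_area)), 1)
    for i in rng.choice(len(ax_px), size=min(n_sw, len(ax_px)), replace=False):
        r = rng.uniform(*spec.swelling_radius_range)
        _paint_disks(canvas, ax_px[i][None, :], r, int(SegClass.AXONAL_SWELLING))

    # disconnected fragments away from the axon
    n_fr = max(int(round(target_fr / 4.0)), 1)
    bg_px = np.argwhere(canvas == 0)
    dist = ndimage.distance_transform_edt(canvas == 0)
    far = bg_px[dist[tuple(bg_px.T)] > 4]
    if len(far):
        for i in rng.choice(len(far), size=min(n_fr, len(far)), replace=False):
            _paint_disks(
                canvas, far[i][None, :], rng.uniform(0.8, 1.3),
                int(SegClass.AXONAL_FRAGMENT),
            )
    return LabelMask(canvas)


def make_segmentation_fixtures(
    n: int,
    spec: AxonSceneSpec | None = None,
    seed: int = 0,
    max_tries: int = 20,
) -> list[tuple[np.ndarray, LabelMask]]:
    """Static labelled (frame, mask) pairs for segmenter training/validation.

    Each scene's class pixel fractions are validated to lie within +-50%
    (relative) of the spec's imbalance profile; infeasible profiles raise
    after ``max_tries`` resampling attempts per scene.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or AxonSceneSpec()
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, LabelMask]] = []
    n_px = spec.shape[0] * spec.shape[1]
    for _ in range(n):
        for attempt in range(max_tries):
            mask = _static_scene(rng, spec)
            frac = mask.class_counts() / n_px
            ok = all(
                0.5 * spec.imbalance[c] <= frac[c] <= 1.5 * spec.imbalance[c]
                for c in (SegClass.AXON, SegClass.AXONAL_SWELLING,
                          SegClass.AXONAL_FRAGMENT)
            )
            if ok:
                break
        else:
            raise RuntimeError(
                "could not achieve the requested class-imbalance profile; "
                "adjust the scene geometry"
            )
        out.append((render_image(mask, spec, rng), mask))
    return out


def make_pattern_dataset(
    n_per_pattern: int,
    T: int = 24,
    seed: int = 0,
    patch_size: int = 64,
    scene: AxonSceneSpec | None = None,
    include_mixed: int = 0,
) -> list[dict]:
    """Labelled transition-histogram sequences for the pattern classifier.

    For each of the four degeneration patterns, ``n_per_pattern`` axons
    are simulated on a ``patch_size`` square patch (kept below the 90-px
    training-patch bound), converted to transition histograms, and tagged
    with a 4-entry multi-hot label vector.  ``include_mixed`` adds samples
    containing two axons with different patterns (two-hot labels).

    Returns dicts with keys ``histograms`` ((T-1, 16) float array),
    ``labels`` ((4,) float array), ``patterns`` (tuple of names).
    """
    if n_per_pattern < 1:
        raise ValueError("n_per_pattern must be >= 1")
    if patch_size >= 90:
        raise ValueError("training patches must stay below 90 px")
    from .temporal_patterns import transition_histograms  # cycle-free at call time

    base = scene or AxonSceneSpec(
        shape=(patch_size, patch_size), n_axons=1, noise_sd=4.0
    )
    rng = np.random.default_rng(seed)
    samples: list[dict] = []

    def one_sample(patterns: tuple[str, ...]) -> dict:
        spec_i = replace(
            base,
            shape=(patch_size, patch_size),
            n_axons=len(patterns),
            seed=int(rng.integers(2**31 - 1)),
        )
        onset = int(rng.integers(max(2, T // 6), max(3, T // 2)))
        # one shared script per axon pattern; simulate each axon separately
        # and overlay masks so each follows its own fate
        canvas_video = None
        for p in patterns:
            script = DegenerationScript(pattern=p, onset_frame=onset)
            _, video = simulate_timelapse(
                replace(spec_i, n_axons=1, seed=int(rng.integers(2**31 - 1))),
                script,
                T,
            )
            arr = video.as_array()
            canvas_video = arr if canvas_video is None else np.where(
                arr > 0, arr, canvas_video
            )
        video = SegmentationVideo.from_array(canvas_video)
        hs = transition_histograms(video)
        labels = np.zeros(4)
        for p in patterns:
            labels[PATTERNS.index(p)] = 1.0
        return {"histograms": hs.H, "labels": labels, "patterns": patterns}

    for p in PATTERNS:
        for _ in range(n_per_pattern):
            samples.append(one_sample((p,)))
    for _ in range(include_mixed):
        pair = tuple(rng.choice(PATTERNS, size=2, replace=False))
        samples.append(one_sample(pair))
    return samples


def evaluator_perturb(
    mask: LabelMask, disagreement_rate: float, seed: int = 0
) -> LabelMask:
    """Synthesize a disagreeing 'second evaluator' from a reference mask.

    Flips each non-background boundary pixel with probability
    ``disagreement_rate`` to the class of a randomly chosen differing
    4-neighbour (typically background), emulating the boundary-dominated
    disagreement between human annotators.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement rate must be in [0, 1]")
    g = mask.grid.copy()
    if disagreement_rate == 0.0:
        return LabelMask(g)
    rng = np.random.default_rng(seed)
    fg = g > 0
    boundary = fg & ~ndimage.binary_erosion(fg, border_value=0)
    coords = np.argwhere(boundary)
    flip = rng.random(len(coords)) < disagreement_rate
    h, w = g.shape
    for y, x in coords[flip]:
        nbrs = []
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and g[yy, xx] != g[y, x]:
                nbrs.append(g[yy, xx])
        if nbrs:
            g[y, x] = nbrs[int(rng.integers(len(nbrs)))]
    return LabelMask(g)
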