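# Methods

This note documents the models, conventions, parameter choices and
limitations of the `entireaxon` package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Class taxonomy and conventions

Four pixel classes with fixed codes: background 0, axon 1, axonal
swelling 2, axonal fragment 3.  Coordinates are 0-based row-major
(row = y, col = x).  Frame 0 maps to `t0_hours` (default 1.5 h, the
first observation after treatment) and frames are `dt_hours` apart
(default 0.5 h); the default recording is therefore 46 frames covering
1.5–24 h.  Mask files store raw codes, so round-trips are bit-exact.
Probability maps are validated to sum to 1 per pixel within 1e-6.
Argmax ties break toward the lowest code, i.e. toward background —
a deliberate conservative-detection bias.

## Preprocessing

16-bit recordings are converted to 8-bit by a linear map from the
*per-stack* global [min, max] to [0, 255] (rounded half-up).  Per-stack
rather than per-frame scaling preserves inter-frame intensity relations,
which the time-course statistics depend on.  Drift is removed by
translation-only registration: each frame's integer shift relative to
frame 0 is estimated by phase correlation, shifts larger than
`max_shift` (default 25 px) are distrusted and zeroed with a warning,
and all frames are cropped to the common valid region so no padding
enters the analysis.  Rotation is not estimated and sub-pixel shifts are
not interpolated: live-cell stage drift is predominantly translational,
and restricting to integer shifts keeps the pipeline exactly
reproducible.  Registration is idempotent and exactly recovers known
integer jitter (tested).

## Segmentation

The segmenter is a U-shaped fully convolutional encoder–decoder with
skip connections and a per-pixel 4-class softmax, trained with the
summed per-pixel cross-entropy (reported per-pixel-mean in the training
curves).  Two encoder depths share the identical contract:

* `reference` — deep encoder (64–512 channels over four resolution levels),
  the reference-scale configuration (8 members, 180 epochs, batch 4,
  Adam, lr 1e-3 decayed 10× every 60 epochs, 512-px crops);
* `small` — two levels (12/24 channels), the desk preset
  (`SegmenterConfig.desk()`: 2 members, 10 epochs, 96-px crops,
  lr 2e-3) that trains in ~1–2 minutes on one CPU and is what every
  test and the acceptance script use.

Augmentation is random cropping, horizontal flipping (p = 0.5) and
rotation by a uniform angle in [−90°, +90°]; the mask is transformed
nearest-neighbour and rotation fills exposed corners with background
(class 0), the neutral class.  Input standardization defaults to
train-set statistics because the synthetic images are not natural
images; grayscale image-net constants (mean 0.449·255, sd 0.226·255)
are selectable.  Pretrained encoder weights are not used — nothing in
the test path downloads anything.  The ensemble prediction is the
arithmetic mean of the members' per-pixel distributions, which
preserves the probability-sum invariant by convexity.  Members are
seeded `seed + member_index`, and training is deterministic for a fixed
seed (single-threaded numpy).

At desk scale the ensemble reliably reaches pooled F1 ≈ 0.87–0.90 for
axon and ≥ 0.997 for background on held-out synthetic scenes; the two
rare classes (swelling 0.6%, fragment 0.2% of pixels) are only
partially recovered at this scale, consistent with their extreme
scarcity — the acceptance thresholds deliberately cover axon and
background only.

## Evaluation

Per class, prediction and reference are binarized and TP/FP/FN pixels
counted (vectorized; tested against a per-pixel double loop).  Recall
and precision with zero denominators are *missing*, never zero.  The
headline statistic is the pooled (micro) mean F1 computed from totals
over all images, which is defined whenever a class occurs anywhere and
avoids the bias of averaging per-image scores under heavy class
imbalance; it equals the harmonic mean of pooled recall and precision
(property-tested).  Consensus labels are strict per-pixel equality of
two annotations; disagreeing pixels are masked out of all counts, for
every class uniformly.

## Quantification

Raw class areas are pixel counts per time point, summed over all videos
of a condition *before* normalization.  Normalization divides by the
total foreground area (axon + swelling + fragment) at the first time
point and multiplies by 100, with the denominator fixed at baseline for
all t; the baseline therefore sums to exactly 100 and values above 100
indicate growth.  A zero baseline raises an error advising exclusion of
the unit (valid recordings contain axons at the first frame).

The AUC readout is implemented exactly as the cumulative form
`Σ (v_i + v_{i+1})·(t_{i+1} − t_i)`, i.e. twice the composite trapezoid
integral.  The doubled form is the package's reported statistic;
`trapezoid=True` (CLI `--trapezoid`) halves it for the conventional
integral.  The identity against an independent `numpy.trapezoid`
integration is property-tested on random series.

The fragmentation mask includes a pixel iff it is axon or swelling at
some frame t and background or fragment at some later frame t′ > t.
Pixels that only ever appear as fragment are excluded: the mask's
purpose is to restrict pattern attribution to regions that demonstrably
degenerated during the recording, and debris present from the start
carries no degeneration event.  The transition need not be the pixel's
final state — a pixel that flickers back does qualify — because
requiring a terminal state would make the mask depend on the recording
end-point.  The mask is monotone under appending frames (tested).

## Pattern classification

**Representation.** For frames t and t+1, each pixel contributes one
count to the bin of its class pair (c1, c2); with 4 classes there are
exactly 16 bins, T frames yield T−1 histograms, and each histogram is
normalized to sum to 1 (empty windows are flagged rather than
normalized).  Histograms are computed over training patches < 90 px and
over 32×32 windows at inference.

**Model.**  The encoder is a multi-layer GRU over the histogram
sequence producing one hidden row per step (V ∈ ℝ^{T×d}).  The decoder
iterates C+1 = 5 steps: attention weights
α_i = softmax(W_att·[s_{i−1}, ReLU(W_in·o_{i−1})]) over the time axis,
context c_i = Vᵀα_i, a GRU state update, and an additive output update
o_i = o_{i−1} + W_out·z_i, starting from o_0 = 0, s_0 = 0.  The final
scores are y = sigmoid(o_5) ∈ (0,1)⁴ — multi-label, no sum constraint
(patterns can co-occur in one axon).  The final decoder state z is the
fixed-length sample representation exposed for t-SNE embedding and any
downstream clustering (`embed_representations`; the package ships no
fixed cluster count — the number of clusters is a free analysis choice).
Attention logits of padded time steps are masked to −∞, so α is a
probability distribution over real steps only; W_att is sized to the
model's `max_steps` at construction and shorter sequences are padded.

**Training.**  Multi-label binary cross-entropy on the logits, LAMB
optimizer (Adam with a per-parameter trust ratio ‖w‖/‖update‖ and
decoupled weight decay; Adam and SGD are selectable).  Reference-scale
defaults mirror a large-data regime (d = 256, 3 GRU layers, dropout
0.9, 60 epochs, batch 128, lr 0.01 decayed 10× every 15 epochs, weight
decay 1e-4).  The desk preset (`RNNConfig.desk()`: d = 48, 2 layers,
dropout 0.1, batch 16, lr 0.02 decayed once) trains in seconds; the
reference dropout of 0.9 is far too aggressive for a 48-unit model on
48 samples, so the desk preset lowers it.

**Erosion augmentation.**  Each training video additionally appears as
three eroded versions (plus three unchanged copies, so the original
keeps a 50% draw probability).  Erosion uses an explicit plus-shaped
(cross) kernel of size 3, 5 or 7 applied to the union of non-background
pixels; eroded-away pixels revert to background and survivors keep
their class.  This emulates thinner axons.

**Inference.**  Non-overlapping 32×32 windows by default (stride
configurable); windows without fragmentation-mask pixels are skipped.
A pattern is called in a window when its sigmoid score exceeds 0.5 (the
sigmoid midpoint), and a called pattern marks all fragmentation-mask
pixels of the window — the simplest attribution consistent with
window-level classification.  Pattern percentages divide by the
fragmentation-mask size; because calls are multi-label they need not
sum to 100.

**Cross-validation.**  10 disjoint folds covering the dataset, built by
per-class round-robin so every fold contains at least one sample of
every pattern (relaxed with a warning when a class is scarcer than the
fold count).  All held-out predictions are pooled and per-pattern
precision/recall/F1 computed from total TP/FP/FN, mirroring the pooled
segmentation scoring.

## The synthetic-data generator

The generator is first-class, tested code and the package's test
substrate.  Axons are smooth random-walk polylines rasterized with a
Gaussian-like circular cross-section (width default 2 px); swellings
are disks (radius 2–3.2 px) centred on the shaft; fragments are small
separated disks.  Images are rendered as background level 40 plus
class-specific intensity increments (axon +55, swelling +85, fragment
+65), lightly blurred, with a dark ring around foreground
(phase-contrast halo mimic, amplitude 18) and Gaussian noise (sd 5) on
the 8-bit scale.  Static scenes target the strongly imbalanced regime
of sparse axonal cultures (~96.4% background / 2.77% axon / 0.58%
swelling / 0.23% fragment) and are validated at generation to lie
within ±50% (relative) of that profile.

The four degeneration scripts follow the biological definitions:
granular — the whole axon converts at onset into separated granules
that fade; retraction — the distal tip pulls back at constant speed
(default 4 px/frame) and the remaining stub fragments; swelling —
swellings grow (default 0.35 px/frame) for 8 frames, then the axon
fragments; transport — constant-size swellings travel along the shaft
(default 3 px/frame), halt at onset, and the axon fragments 6 frames
later; none — continued growth.  All degenerating fates end in granular
fragmentation, as observed biologically; within a short recording the
retraction script may not reach its terminal fragmentation phase, which
is itself realistic.  A centroid classifier on summed histograms
separates the four scripts above chance (tested), so the sequence-
classification task is well-posed before any recurrent model is
involved.

What the generator does *not* emulate: photorealistic phase-contrast
optics, illumination drift, crossing/overlapping axon bundles, debris,
focus changes, and dose–response kinetics (an insult's severity appears
only through onset time and kinetic parameters).  Passing tests
therefore demonstrate that the implementation is correct and that the
architecture can learn the intended signal — not that the shipped
desk-scale weights transfer to real microscopy, which requires training
on annotated recordings at reference scale.

## Numerical choices

* All computation is float64 numpy; the autodiff stack
  (`entireaxon.nn`) is covered by central finite-difference gradient
  tests for every operation, including backpropagation through time of
  the GRU.
* Cross-entropy on probability maps clips logs at 1e-12; network
  training uses the fused log-softmax form.  The multi-label loss uses
  the numerically stable `max(x,0) − x·t + log1p(exp(−|x|))` form.
* Max-pooling breaks ties toward the first element of the 2×2 block;
  histogram/argmax ties break toward the lowest class code.
* Inputs whose sides are not divisible by the network's pooling factor
  are edge-padded for prediction and the logits cropped back.
* Problem sizes in the tests and acceptance script (30+6 scenes of
  128×128 px for segmentation; 48 sequences of 24 frames at 64×64 px
  for patterns) were chosen as the package's desk-scale study
  conditions: large enough for stable pooled statistics, small enough
  to train both models from scratch in a few minutes on one CPU.

## Known limitations

* Translation-only alignment cannot correct rotational drift.
* Desk-scale segmentation under-detects the two rare classes; swollen
  and fragmented pixels require reference-scale training for reliable
  per-class recovery.
* Window-level pattern attribution marks all fragmentation-mask pixels
  of a called window; sub-window localization is not attempted.
* The histogram representation discards all spatial arrangement within
  a window; patterns distinguishable only by geometry (not by class
  flux) would be invisible to it.
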