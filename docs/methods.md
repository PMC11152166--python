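# Methods

## Model

The classifier is a (2+1)D residual network for short grayscale video
clips, channels-last `(L, H, W, 1)`. Every 3D convolution is factorised
into a spatial convolution with kernel 1×3×3 and a temporal convolution
with kernel 3×1×1; this keeps 3D spatio-temporal feature extraction while
spending far fewer parameters and operations than full 3×3×3 kernels. A
residual block is

```
[spatial 1×3×3 → BN → ReLU → temporal 3×1×1 → BN → ReLU] × 2  (+ shortcut)
```

with the additive shortcut applied after the second bracket and no extra
post-add activation. A stride-2 block halves frames, height and width in
its leading convolution (the spatial kernel has temporal extent 1, so its
temporal stride is plain frame subsampling) and projects the shortcut with
a strided 1×1×1 convolution plus BN. The stem is a 1×3×3 convolution
(stride 1×2×2) → BN → ReLU → 1×2×2 max pool; the head is a 3D global
*average* pool and a fully connected softmax layer. Average pooling is
used so the embedding variant can reuse the pooled features directly.

Default configuration: stem 16 filters; four stages of two blocks with
40/96/192/256 filters and strides 1/2/2/2; input 12×128×128×1; 10 classes.
This totals **5,154,594 trainable parameters (~5.2 M)** — convolution and
dense weights and biases plus BN scale/offset — and **3.745 GFLOPs
(~3.7 G)** for one forward pass, counting 2 operations per
multiply-accumulate for convolutions and dense layers only (BN and
activations are negligible and excluded). The counting convention is
isolated in one function (`count_flops(..., ops_per_mac=...)`) so the
1-op-per-MAC alternative is a flag away. The per-stage widths are a
calibration choice: the architecture family is fixed by the block
structure above, and the widths were selected so that the parameter and
operation totals land on the published scale; they are config-overridable.

Two variants share the backbone:

- **Embedder**: the classification layer is replaced by a linear fully
  connected layer with the same width as the pooled features (256 by
  default) followed by L2 normalisation, trained with semi-hard triplet
  loss.
- **2D baseline**: a standard ResNet-18-style 2D network (stem 7×7/64,
  stages 2-2-2-2 × 64/128/256/512, ~11.2 M parameters at 10 classes)
  consuming only the first frame of each clip, used to quantify the
  contribution of temporal information. Its max pool is non-overlapping
  2×2 (parameter count is unaffected).

### Numerical core

No deep-learning framework is used: layers are implemented in NumPy with
explicit forward/backward passes (im2col convolutions, batch norm with
running statistics for evaluation, first-occurrence argmax pooling with
exact gradient routing, Adam with bias correction, eps 1e−7). Everything
is float32 and fully seeded; evaluation-mode forward passes are
bit-reproducible. Backpropagation is verified against central finite
differences in the tests. Batch-norm running statistics are seeded from
the first training batch and updated with momentum 0.9, which keeps
evaluation-mode behaviour sensible after the short training runs used on
CPU.

### Losses

- Classification: mean softmax cross-entropy over sparse integer labels.
- Metric learning: semi-hard triplet loss on squared Euclidean distances.
  For each anchor–positive pair the semi-hard negative is the *nearest*
  negative farther from the anchor than the positive; if none exists the
  farthest negative is used. The loss `max(0, d(a,p) − d(a,n) + margin)`
  is averaged over anchor–positive pairs (margin default 1.0; mining
  treated as constant in the gradient, the standard subgradient). Squared
  distances are monotone in distance, so the mining order is unchanged and
  the gradient is exact. Batches are class-balanced (at least two classes
  with two samples each); batches without a valid triplet are skipped and
  counted.

## Training protocol

Protocol defaults mirror the full-scale recipe: Adam at a fixed 1e−6 for
50 epochs, batch 32, for the classifier; 1e−3 for 20 epochs for the
embedder. Final-epoch weights are used — no early stopping and no
best-validation checkpointing; the validation split is monitored only.
Repeat runs (default 3 seeds) re-draw both the data split and the weight
initialisation. The CPU-scale experiments bundled with the package use the
same loops with a tiny spec (8×32×32×1 input, stages 8/16) and a learning
rate of 1e−3 for 8–30 epochs, since a 1e−6 rate cannot move a freshly
initialised tiny network in a handful of epochs.

## Event-timing extraction

Applying the classifier to each imaged hour gives a probability
trajectory (hours × 10, rows summing to 1). Onsets are extracted per
event, reading only that event's column (so event timings can decouple
independently — the signature of heterochrony):

- **peak** (Gastrula…Crawling): the hour of the column maximum; exact
  ties resolve to the earliest hour, and a recurring class reports its
  earliest global maximum.
- **threshold** (Radula 0.6, Hatch 0.4, Dead 0.3): the earliest hour with
  probability *strictly* greater than the threshold; absent if never
  exceeded.
- Pre-Gastrula marks development before the first event and is excluded.

No smoothing is applied by default; an optional moving average is
available but off. Missing hours are skipped, never interpolated, and
onsets are reported on the imaged-hour grid. Absent events are reported as
absent, not as sentinels. `calibrate_thresholds` grid-searches per-event
thresholds against annotated onsets by mean absolute error (ties to the
lower threshold).

## Thermal summaries

Per (temperature, event): mean onset hour, s.d. (0 with a flag when n=1)
and n, excluding Pre-Gastrula; embryos lacking an event reduce n and are
never imputed. Developmental rate is 1/mean onset (h⁻¹); T_opt is the
assayed temperature with the highest rate, reported on the assay grid
(ties to the lower temperature) — no curve fitting, since treatments are
compared directly. Error bars in the plotting helpers are ±1 s.d.

## Synthetic data generator

The generator renders hourly clips of an egg-bounded "embryo": a bright
capsule ring enclosing a motif drawn analytically per frame. Each of the
10 event classes maps to exactly one motif — a spatial pattern (soft
blob, blob with dark spots, shelled blob with a bright crescent, empty
capsule, speckled decaying texture) plus a parametric motion (none,
sinusoidal intensity pulse, rigid rotation, oscillating translation, slow
drift). Motions are deterministic functions of the frame timestamp with
neutral phase at t=0, so Fourier and displacement oracles exist, and a
clip is a pure function of (motif, seed): regeneration is bit-identical.
Noise is additive Gaussian clipped to 8-bit (salt-and-pepper is reserved
for the augmentation stage to avoid confounds). Frames default to 64×64
(128×128 works, 32×32 is used by the CPU experiments); full-scale
schedules default to 20 s clips at 30 frames/s.

Per-embryo series follow the annotation rule — each hour is labelled with
the latest event whose onset has passed, Pre-Gastrula before the first.
Within an event's span the rendered signature *fades*: motion amplitude,
decorations and the deviation from a neutral mid-grey blob decay
exponentially with hours since onset (time constant 1.5 h; terminal
events, Hatch and Dead, never fade). This models the observation that an
embryo is most characteristic of an event right when it begins, and it is
what makes classifier probability trajectories peak at the onset hour
rather than drifting across the span; with piecewise-constant appearance
(fading disabled) the peak's position within a span is decided by noise.

`make_temporal_only_pair` returns two motifs that are identical in every
static respect and differ only in motion; rendered with matched seeds
their first frames are bit-identical, so any first-frame classifier is at
chance *by construction* while the video classifier can exploit the
pulse. `thermal_timings` draws per-embryo event onsets across the eight
assay temperatures (15–32.5 °C) from normal distributions around means set
by a quadratic thermal performance curve, with the built-in optimum 2.5 °C
lower for late events (Crawling, Radula, Hatch: 25 °C vs 27.5 °C) — the
ground truth for T_opt-shift recovery. Baseline onset hours (Gastrula 6 h
… Hatch 150 h at the optimum, CV 5 %) are on the scale of pond-snail
development at warm temperatures.

What the generator does *not* emulate: real embryo morphology and its
growth, egg-localisation/cropping artefacts, illumination drift, focus
changes, or inter-embryo appearance variability beyond noise and schedule
jitter. Passing tests therefore demonstrate that the pipeline's machinery
is correct and that its rules behave as specified on videos whose
spatio-temporal statistics are known — not that the bundled tiny models
would reach any particular accuracy on real microscopy data.

## Augmentation

Plans are deterministic per (sample id, seed): horizontal/vertical flips,
pixel amplification ×{0.5, 1, 2}, salt-and-pepper noise and Gaussian blur,
each optional augmentation enabled independently with probability 0.5,
blur sigma uniform in [0.5, 1.5] px and salt-and-pepper fraction 0.02 —
activation probabilities and magnitudes are configuration choices exposed
in the config, not data-derived facts. The identical transform (including
the noise mask) applies to every frame of a clip. Selective balancing
upsamples each class with augmented copies of its own clips (uniform with
replacement; identity plans re-drawn) until all classes equal the
pre-balancing maximum; a non-selective mode adds equal numbers of copies
per class, leaving imbalance in place, for comparison.

## CPU-scale reference experiments

`devevent.experiments` packages five self-contained studies sized for a
single CPU (tiny spec, 32×32 clips at the effective 3 frames/s sampling of
the full protocol, 3 repeat seeds):

1. **Temporal information**: 2 temporal-only classes, 200 training / 100
   test clips, 3 seeds; reports the 3D–2D top-1 gap and a binomial test of
   the 2D baseline against chance.
2. **Timing recovery**: 12 training + 20 evaluation embryos with known
   schedules (~2,000 hourly clips total); reports the fraction of
   embryo–event pairs recovered within ±1 h.
3. **Triplet separation**: 3 classes × 40/20 train/test clips; reports
   intra/inter distances, unit-norm deviation and 2D-PCA silhouette.
4. **Stride sweep**: strides {3, 5, 10} over 4 s of footage on 4 static
   (purely spatial) classes; reports per-stride accuracies and whether
   mean ± 2 s.e. bands overlap (the expected null).
5. **Thermal recovery**: 20 embryos × 8 temperatures of synthetic
   timings; reports recovered T_opt for early vs late events.

These sizes are the package's standing study conditions; the acceptance
script and the test suite run exactly these.

## Design choices and limitations

- Resize uses local-mean (area) interpolation for downscaling (bilinear
  for upscaling); pixels are scaled to [0, 1] only at the model boundary,
  stored datasets stay 8-bit. Frames are resized directly to squares;
  source acquisitions are near-square so aspect distortion is negligible,
  but non-square crops would be stretched.
- Hour stamps are integers and frame indexing is 0-based.
- GIF is the on-disk clip format (lossless for 8-bit grayscale); TIFF
  frame directories (`<embryo>_t<hour>_f<frame>.tif`, numeric ordering)
  are accepted on input.
- The temporal-vs-spatial contrast and the stride null are *constructed*
  properties of the synthetic bench, chosen to mirror the corresponding
  full-scale comparisons qualitatively; they are not re-measurements of
  those results.
- One global seed fans out to stage-specific seeds via a stable hash, so
  pipeline stages are independently reproducible.
- Egg detection/localisation is out of scope; inputs are assumed already
  cropped to the egg (a configurable crop/resize stands in for the
  localisation stage).
- UMAP is a delegated, pinned-parameter stage (n_neighbors 15,
  n_components 2, Euclidean, min_dist 0.1, seeded); tests assert only
  topology-level properties of projections.
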