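# devevent

Automated detection of developmental event onsets in embryo time-lapse
video, built around a small (2+1)D residual video classifier.

## The problem

Developmental events — gastrulation, the first heartbeat, the onset of
crawling, hatching — are biology's time-stamps for comparing development
across treatments, stages and species. Scoring them by eye from time-lapse
video is slow and subjective, and many events (cardiac activity, radula
movement) are invisible in a single still image: they are defined by
*motion*. `devevent` implements a video classifier that uses both spatial
and temporal features, plus everything around it:

- a **(2+1)D residual network** ("Dev-ResNet" style): each 3D convolution
  is factorised into a 2D spatial convolution (1×3×3) followed by a 1D
  temporal convolution (3×1×1), with batch norm and ReLU, residual
  shortcuts, a 3D global average pool and a softmax head over the 10-event
  taxonomy (Pre-Gastrula, Gastrula, Trochophore, Veliger, Eye spots,
  Heart beat, Crawling, Radula, Hatch, Dead). The default configuration
  has ~5.2 M parameters and needs ~3.7 GFLOPs per 12×128×128×1 clip.
- **clip I/O**: TIFF frame sequences and GIF clip datasets, temporal
  subsampling (every 10th of the first 120 frames → 12-frame clips,
  i.e. 3 sampled frames per second of 30 frames/s footage), 80:10:10
  splits.
- **selective augmentation**: sample-deterministic flips, 0.5×/2×
  intensity, salt-and-pepper noise and Gaussian blur (identical transform
  on every frame of a clip), used to upsample minority classes until all
  classes match the maximum count.
- **training**: sparse categorical cross-entropy with Adam (protocol
  defaults: learning rate 1e−6, 50 epochs, batch 32), plus a triplet
  semi-hard embedding variant (L2-normalised linear head, learning rate
  1e−3, 20 epochs) for visualising development as a continuum.
- **event timing**: applying the classifier to every imaged hour yields a
  per-embryo probability trajectory; onsets are extracted per event with a
  *peak* rule (hour of maximum probability, Gastrula…Crawling) or a
  *threshold* rule (first hour strictly above a per-event threshold:
  Radula 0.6, Hatch 0.4, Dead 0.3), with Pre-Gastrula excluded.
- **thermal summaries**: mean ± s.d. onset per (temperature, event),
  developmental rate 1/onset, and T_opt — the assay temperature with the
  highest rate — to detect stage-specific thermal sensitivity.
- **synthetic bench**: a deterministic generator of egg-bounded "embryo"
  videos with known event schedules (distinct spatial motifs and analytic
  motions per event), so the entire pipeline is testable on CPU without
  any external data.

The neural network core (convolutions, batch norm, pooling, Adam, both
losses) is a compact NumPy implementation with explicit forward/backward
passes — deterministic, dependency-light and fast enough for the bundled
CPU-scale experiments.

## Worked example

```python
import numpy as np
from devevent import (
    default_schedule, generate_embryo_series, tiny_spec, build_classifier,
    TrainConfig, train_classifier, ArrayDataset, standardize_clip,
    predict_trajectory, extract_timing, Clip, ClipDataset,
)

rng = np.random.default_rng(0)

# 1. synthesise a training cohort with known schedules (8 frames/hourly clip)
cohort = []
for i in range(12):
    sched = default_schedule(f"train{i}", rng, frame_rate=3.0, clip_seconds=8 / 3)
    tl, ann = generate_embryo_series(sched, seed=100 + i, size=32)
    cohort.append((sched, tl))

# 2. label every hourly clip by the previous-event rule and train
clips = [(sched.label_at(h), c) for sched, tl in cohort for h, c in zip(tl.hours, tl.clips)]
x = np.stack([standardize_clip(c, 32) for _, c in clips])
y = np.array([int(lab) for lab, _ in clips])
net = build_classifier(tiny_spec(input_shape=(8, 32, 32, 1)), seed=0)
net, hist = train_classifier(net, ArrayDataset(x, y), None,
                             TrainConfig(learning_rate=1e-3, epochs=30, seed=0))

# 3. predict a held-out embryo's trajectory and extract onsets
sched = default_schedule("test0", rng, frame_rate=3.0, clip_seconds=8 / 3)
tl, _ = generate_embryo_series(sched, seed=999, size=32)
traj = predict_trajectory(net, tl, size=32, stride=1, n_source_frames=8)
timing = extract_timing(traj)
print({ev.display_name: h for ev, h in timing.onsets.items()})
print({ev.display_name: h for ev, h in sched.onsets.items()})
```

Output:

```
{'Gastrula': 4, 'Trochophore': 5, 'Veliger': 7, 'Eye spots': 10, 'Heart beat': 14, 'Crawling': 18, 'Radula': 20, 'Hatch': 22}
{'Gastrula': 3, 'Trochophore': 5, 'Veliger': 7, 'Eye spots': 9, 'Heart beat': 13, 'Crawling': 17, 'Radula': 20, 'Hatch': 22}
```

The first line is the extracted onsets, the second the generator's
ground-truth schedule: every event is recovered within ±1 hour. Across 20
held-out embryos (160 embryo–event pairs), 95–100 % of onsets land within
±1 hour (see below).

The same pipeline is available from the shell:

```bash
devevent synth --config cfg.yaml --out run/
devevent build-dataset --timelapses run/timelapses --annotations run/annotations.csv --out run/
devevent train --dataset run/dataset --out run/
devevent predict --weights run/weights.npz --timelapses run/timelapses --out run/
devevent extract-events --trajectories run/trajectories --out run/
devevent summarize --timings run/timings.csv --out run/
devevent model-summarize   # layer table, ~5.2M parameters, ~3.7 GFLOPs
```

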