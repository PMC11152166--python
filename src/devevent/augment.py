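"""Sample-deterministic video augmentation and selective class balancing.

Augmentations are deterministic on a sample-specific basis: the plan drawn
for a sample id fully determines the transform, and the *same* transform —
including the same salt-and-pepper noise mask — is applied to every frame
of the clip, so no spurious temporal signal is injected.

Selective balancing upsamples every under-represented class with augmented
copies of its own clips until all classes match the pre-balancing maximum
count; originals are retained unmodified.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .video_io import ClipDataset, frames_4d

INTENSITY_FACTORS = (0.5, 1.0, 2.0)

# Activation probabilities and magnitudes are configuration, not data facts:
# each of the four optional augmentations is enabled independently with
# probability 1/2, the intensity factor is uniform over {0.5, 1, 2}.
DEFAULT_P_ENABLE = 0.5
DEFAULT_SALT_PEPPER_FRACTION = 0.02
DEFAULT_BLUR_SIGMA_RANGE = (0.5, 1.5)


@dataclass(frozen=True)
class AugmentationPlan:
    """A fully resolved, sample-deterministic augmentation."""

    sample_id: str
    flip_h: bool
    flip_v: bool
    intensity_factor: float
    salt_pepper_fraction: float  # 0 disables
    gaussian_blur_sigma: float  # 0 disables
    seed: int  # drives the noise mask only

    @property
    def is_identity(self) -> bool:
        return (
            not self.flip_h
            and not self.flip_v
            and self.intensity_factor == 1.0
            and self.salt_pepper_fraction == 0.0
            and self.gaussian_blur_sigma == 0.0
        )


def _plan_rng(sample_id: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def sample_plan(
    sample_id: str,
    seed: int,
    p_enable: float = DEFAULT_P_ENABLE,
    salt_pepper_fraction: float = DEFAULT_SALT_PEPPER_FRACTION,
    blur_sigma_range: tuple[float, float] = DEFAULT_BLUR_SIGMA_RANGE,
) -> AugmentationPlan:
    """Draw a reproducible plan for ``(sample_id, seed)``.

    Each augmentation type (horizontal flip, vertical flip, salt-and-pepper
    noise, Gaussian blur) is enabled independently; pixel amplification is
    one of 0.5x, 1x or 2x.
    """
    rng = _plan_rng(sample_id, seed)
    flip_h = bool(rng.random() < p_enable)
    flip_v = bool(rng.random() < p_enable)
    intensity = float(rng.choice(INTENSITY_FACTORS))
    sp = salt_pepper_fraction if rng.random() < p_enable else 0.0
    blur = float(rng.uniform(*blur_sigma_range)) if rng.random() < p_enable else 0.0
    noise_seed = int(rng.integers(0, 2**31))
    return AugmentationPlan(sample_id, flip_h, flip_v, intensity, sp, blur, noise_seed)


def apply_plan(plan: AugmentationPlan, clip: np.ndarray) -> np.ndarray:
    """Apply a plan to an 8-bit grayscale clip ``(L, H, W, 1)``.

    Every frame receives the identical transform; output is clipped to the
    8-bit range and keeps the input shape.
    """
    frames = frames_4d(clip)
    out = frames.astype(np.float32)
    if plan.flip_h:
        out = out[:, :, ::-1, :]
    if plan.flip_v:
        out = out[:, ::-1, :, :]
    if plan.intensity_factor != 1.0:
        out = out * plan.intensity_factor
    if plan.gaussian_blur_sigma > 0:
        out = gaussian_filter(out, sigma=(0, plan.gaussian_blur_sigma, plan.gaussian_blur_sigma, 0))
    if plan.salt_pepper_fraction > 0:
        h, w = out.shape[1:3]
        rng = np.random.default_rng(plan.seed)
        n = int(round(plan.salt_pepper_fraction * h * w))
        ys = rng.integers(0, h, n)
        xs = rng.integers(0, w, n)
        vals = rng.choice([0.0, 255.0], n)
        out[:, ys, xs, 0] = vals  # same mask on every frame
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def balance_classes(
    dataset: ClipDataset,
    seed: int = 0,
    selective: bool = True,
    n_copies: int | None = None,
) -> ClipDataset:
    """Remove class imbalance by selective augmentation upsampling.

    With ``selective=True`` (default) every class is upsampled with
    augmented copies until its count equals the pre-balancing maximum.
    With ``selective=False`` every class instead gains the same number of
    augmented copies (``n_copies``, default the maximum deficit), growing
    the dataset while leaving imbalances in place — the non-selective
    comparison arm.

    Copies are drawn uniformly with replacement from the class's original
    clips; an identity plan is re-drawn so augmented copies always differ
    from their source.
    """
    counts = dataset.class_counts()
    if not counts:
        raise ValueError("cannot balance an empty dataset")
    empty = [lab.display_name for lab, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"classes with no samples: {empty}")
    max_count = max(counts.values())
    rng = np.random.default_rng(seed)

    clips = list(dataset.clips)
    labels = list(dataset.labels)
    ids = list(dataset.sample_ids)
    if n_copies is None:
        n_copies = max(max_count - c for c in counts.values())
    for lab in sorted(counts, key=int):
        deficit = (max_count - counts[lab]) if selective else n_copies
        src_idx = [i for i, l in enumerate(dataset.labels) if l == lab]
        for k in range(deficit):
            i = int(rng.choice(src_idx))
            new_id = f"{dataset.sample_ids[i]}#aug{k}"
            plan = sample_plan(new_id, seed)
            attempt = 0
            while plan.is_identity:
                attempt += 1
                plan = sample_plan(f"{new_id}~{attempt}", seed)
            clips.append(apply_plan(plan, dataset.clips[i]))
            labels.append(lab)
            ids.append(new_id)
    return ClipDataset(clips, labels, ids)
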