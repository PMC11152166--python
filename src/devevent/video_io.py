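"""Reading, assembling and writing embryo time-lapse video.

A time-lapse experiment images each embryo for a short clip every hour.
On disk a clip is either a directory of single-frame TIFFs (the format a
microscope acquisition loop emits) or a single animated GIF; in memory it
is an 8-bit grayscale frame stack ``(L, H, W, 1)``.

The documented TIFF naming pattern is ``<embryo>_t<hour>_f<frame>.tif``;
hours and frames are ordered numerically, never lexically.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.transform import resize, resize_local_mean

from .taxonomy import EventLabel

TIFF_PATTERN = re.compile(r"(?P<embryo>.+)_t(?P<hour>\d+)_f(?P<frame>\d+)\.tiff?$")


@dataclass
class Clip:
    """A fixed-length grayscale frame stack ``(L, H, W, 1)``, 8-bit."""

    frames: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim == 3:
            f = f[..., None]
        if f.ndim != 4 or f.shape[-1] != 1:
            raise ValueError(f"clip frames must be (L, H, W, 1); got {f.shape}")
        if f.shape[0] < 1:
            raise ValueError("clip must contain at least one frame")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames.shape


@dataclass
class TimeLapse:
    """Ordered hourly clip series for one embryo."""

    embryo_id: str
    hours: list[int]
    clips: list[Clip]

    def __post_init__(self):
        if len(self.hours) != len(self.clips):
            raise ValueError("hours and clips must have equal length")
        if any(b <= a for a, b in zip(self.hours, self.hours[1:])):
            raise ValueError("hours must be strictly increasing")


@dataclass
class AnnotationTable:
    """Ground-truth event onsets: rows of (embryo_id, event, onset_hour).

    An optional ``treatment`` column carries the assay temperature (°C).
    """

    df: pd.DataFrame

    REQUIRED = ("embryo_id", "event", "onset_hour")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        # one onset per (embryo, event)
        dup = self.df.duplicated(subset=["embryo_id", "event"])
        if dup.any():
            raise ValueError("duplicate (embryo_id, event) rows in annotation table")
        self.df = self.df.reset_index(drop=True)
        self.df["event"] = [EventLabel.from_name(str(e)).display_name for e in self.df["event"]]

    def onsets_for(self, embryo_id: str) -> dict[EventLabel, int]:
        sub = self.df[self.df["embryo_id"] == embryo_id]
        return {
            EventLabel.from_name(r.event): int(r.onset_hour) for r in sub.itertuples()
        }

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "AnnotationTable":
        return cls(pd.DataFrame(rows))


def write_timelapse_tiffs(tl: TimeLapse, out_dir: str | Path) -> Path:
    """Write a time-lapse as single-frame TIFFs under the documented pattern."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for hour, clip in zip(tl.hours, tl.clips):
        for fi in range(clip.n_frames):
            tifffile.imwrite(
                out / f"{tl.embryo_id}_t{hour}_f{fi}.tif", clip.frames[fi, :, :, 0]
            )
    return out


def concat_tiff_sequence(frame_dir: str | Path) -> TimeLapse:
    """Assemble per-hour clips from a directory of single-frame TIFFs.

    Frames are grouped by hour and ordered by their numeric frame index
    (``_f2`` sorts before ``_f10``).  A missing hour raises a warning and
    is recorded as a gap; an unreadable frame raises an error naming the
    file.
    """
    frame_dir = Path(frame_dir)
    groups: dict[int, list[tuple[int, Path]]] = {}
    embryos = set()
    for path in sorted(frame_dir.iterdir()):
        m = TIFF_PATTERN.match(path.name)
        if not m:
            continue
        embryos.add(m.group("embryo"))
        groups.setdefault(int(m.group("hour")), []).append((int(m.group("frame")), path))
    if not groups:
        raise FileNotFoundError(f"no frames matching the TIFF pattern in {frame_dir}")
    if len(embryos) > 1:
        raise ValueError(f"multiple embryos in {frame_dir}: {sorted(embryos)}")
    embryo_id = embryos.pop()

    hours = sorted(groups)
    missing = sorted(set(range(hours[0], hours[-1] + 1)) - set(hours))
    if missing:
        warnings.warn(f"missing hours in {frame_dir}: {missing}", stacklevel=2)

    clips = []
    for hour in hours:
        frames = []
        for _, path in sorted(groups[hour]):
            try:
                frames.append(tifffile.imread(path))
            except Exception as exc:  # noqa: BLE001 - re-raise with the file name
                raise IOError(f"unreadable frame {path}: {exc}") from exc
        clips.append(Clip(np.stack(frames)[..., None], source_id=f"{embryo_id}:h{hour}"))
    return TimeLapse(embryo_id, hours, clips)


def _write_gif(frames: np.ndarray, path: Path) -> None:
    imgs = [Image.fromarray(frames[i, :, :, 0].astype(np.uint8), mode="L") for i in range(frames.shape[0])]
    imgs[0].save(path, save_all=True, append_images=imgs[1:], loop=0, duration=33, optimize=False)


def _read_gif(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        frames = []
        for i in range(getattr(im, "n_frames", 1)):
            im.seek(i)
            frames.append(np.array(im.convert("L"), dtype=np.uint8))
    return np.stack(frames)[..., None]


GIF_PATTERN = re.compile(r"(?P<embryo>.+)_t(?P<hour>\d+)\.gif$")


def write_timelapse_gifs(tl: TimeLapse, out_dir: str | Path) -> Path:
    """Write a time-lapse as one GIF per hour (``<embryo>_t<hour>.gif``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for hour, clip in zip(tl.hours, tl.clips):
        _write_gif(clip.frames, out / f"{tl.embryo_id}_t{hour}.gif")
    return out


def read_timelapse(in_dir: str | Path) -> TimeLapse:
    """Read a time-lapse from per-hour GIFs or single-frame TIFFs."""
    in_dir = Path(in_dir)
    gifs = [(p, GIF_PATTERN.match(p.name)) for p in sorted(in_dir.iterdir())]
    gifs = [(p, m) for p, m in gifs if m]
    if not gifs:
        return concat_tiff_sequence(in_dir)
    embryos = {m.group("embryo") for _, m in gifs}
    if len(embryos) > 1:
        raise ValueError(f"multiple embryos in {in_dir}: {sorted(embryos)}")
    embryo_id = embryos.pop()
    by_hour = sorted((int(m.group("hour")), p) for p, m in gifs)
    hours = [h for h, _ in by_hour]
    clips = [Clip(_read_gif(p), source_id=f"{embryo_id}:h{h}") for h, p in by_hour]
    return TimeLapse(embryo_id, hours, clips)


def subsample_clip(
    clip: Clip, start_frame: int = 0, n_source_frames: int = 120, stride: int = 10
) -> Clip:
    """Keep every ``stride``-th of ``n_source_frames`` frames from ``start_frame``.

    Yields exactly ``ceil(n_source_frames / stride)`` frames: the default
    120 source frames at stride 10 become a 12-frame clip, i.e. 3 sampled
    frames per second of 30 frames/s footage.
    """
    need = start_frame + n_source_frames
    if clip.n_frames < need:
        raise ValueError(
            f"clip {clip.source_id!r} has {clip.n_frames} frames; "
            f"need at least {need} (start_frame={start_frame}, "
            f"n_source_frames={n_source_frames})"
        )
    sub = clip.frames[start_frame:need:stride]
    return Clip(sub.copy(), source_id=clip.source_id)


def standardize_clip(clip: Clip | np.ndarray, size: int = 128) -> np.ndarray:
    """Grayscale, resize to ``size x size`` and scale to [0, 1] float32.

    Downscaling uses local-mean (area) interpolation, which is anti-aliased
    and reproducible; upscaling uses bilinear interpolation.
    """
    frames = clip.frames if isinstance(clip, Clip) else np.asarray(frames_4d(clip))
    l, h, w, c = frames.shape
    if c == 3:
        frames = (
            0.299 * frames[..., 0] + 0.587 * frames[..., 1] + 0.114 * frames[..., 2]
        )[..., None]
    x = frames[..., 0].astype(np.float32)
    if (h, w) != (size, size):
        if h >= size and w >= size:
            x = np.stack([resize_local_mean(f, (size, size)) for f in x])
        else:
            x = np.stack(
                [resize(f, (size, size), order=1, anti_aliasing=False, preserve_range=True) for f in x]
            )
    return (x[..., None] / 255.0).astype(np.float32)


def frames_4d(arr: np.ndarray) -> np.ndarray:
    """Coerce a (L, H, W) or (L, H, W, C) array to 4D."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError(f"expected 3D or 4D frame stack, got shape {arr.shape}")
    return arr


def split_dataset(samples, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Random disjoint train/validation/test partition.

    Sizes follow the fractions up to rounding; the split is reproducible
    for a fixed seed and exhaustive (the union equals the input).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(samples)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_val = min(n_val, n - n_train)
    idx_train, idx_val, idx_test = (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )
    pick = lambda idx: [samples[i] for i in idx]  # noqa: E731
    return pick(idx_train), pick(idx_val), pick(idx_test)


@dataclass
class ClipDataset:
    """Labelled clips: the unit datasets the trainers consume."""

    clips: list[np.ndarray] = field(default_factory=list)  # each (L, H, W, 1) uint8
    labels: list[EventLabel] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.clips) == len(self.labels) == len(self.sample_ids)):
            raise ValueError("clips, labels and sample_ids must have equal length")

    def __len__(self) -> int:
        return len(self.clips)

    def subset(self, indices) -> "ClipDataset":
        return ClipDataset(
            [self.clips[i] for i in indices],
            [self.labels[i] for i in indices],
            [self.sample_ids[i] for i in indices],
        )

    def class_counts(self) -> dict[EventLabel, int]:
        counts: dict[EventLabel, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def write_clip_dataset(dataset: ClipDataset, out_dir: str | Path) -> Path:
    """Write clips as animated GIFs plus a label manifest CSV.

    The GIF encoding is lossless for 8-bit grayscale input, so the
    write/read pair round-trips bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for clip, label, sid in zip(dataset.clips, dataset.labels, dataset.sample_ids):
        frames = frames_4d(clip)
        fname = f"{sid}.gif"
        imgs = [Image.fromarray(frames[i, :, :, 0].astype(np.uint8), mode="L") for i in range(frames.shape[0])]
        imgs[0].save(
            out / fname,
            save_all=True,
            append_images=imgs[1:],
            loop=0,
            duration=33,
            optimize=False,
        )
        rows.append({"sample_id": sid, "file": fname, "label": label.display_name})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_clip_dataset(in_dir: str | Path) -> ClipDataset:
    """Read a GIF clip dataset written by :func:`write_clip_dataset`.

    A manifest label outside the event taxonomy is rejected.
    """
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    clips, labels, ids = [], [], []
    for row in manifest.itertuples():
        label = EventLabel.from_name(str(row.label))  # raises on unknown labels
        with Image.open(in_dir / row.file) as im:
            frames = []
            for i in range(getattr(im, "n_frames", 1)):
                im.seek(i)
                frames.append(np.array(im.convert("L"), dtype=np.uint8))
        clips.append(np.stack(frames)[..., None])
        labels.append(label)
        ids.append(str(row.sample_id))
    return ClipDataset(clips, labels, ids)
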