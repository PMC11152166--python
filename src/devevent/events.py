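"""Event probability trajectories and onset-timing extraction.

Applying the classifier to every imaged hour of one embryo's development
yields a probability trajectory: an hours x classes matrix of softmax
outputs.  Event onsets are read from these trajectories with two rules:

* **peak** — events whose probability rises and falls (Gastrula through
  Crawling): the onset is the hour of the column's maximum, earliest hour
  on ties.
* **threshold** — events whose probability rises to a plateau: the onset
  is the first hour with probability strictly greater than a per-event
  threshold (defaults: Radula 0.6, Hatch 0.4, Dead 0.3), absent if never
  exceeded.

Pre-Gastrula is the "before anything happened" class and is excluded from
timing extraction.  Each event's timing is read from its own column only,
so event timings can decouple independently (heterochrony detection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .taxonomy import EventLabel, N_CLASSES
from .train import predict_proba
from .video_io import AnnotationTable, Clip, TimeLapse, standardize_clip, subsample_clip


@dataclass
class ProbabilityTrajectory:
    """Per-embryo hours x classes matrix of class probabilities."""

    embryo_id: str
    hours: np.ndarray
    probs: np.ndarray  # (n_hours, n_classes), rows sum to 1

    def __post_init__(self):
        self.hours = np.asarray(self.hours)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.hours.shape[0]:
            raise ValueError("probs must be (n_hours, n_classes) matching hours")
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("hours must be strictly increasing")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each probability row must sum to 1 (+/- 1e-6)")

    def column(self, event: EventLabel) -> np.ndarray:
        return self.probs[:, int(event)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=[ev.display_name for ev in EventLabel])
        df.insert(0, "hour", self.hours)
        return df

    @classmethod
    def from_frame(cls, embryo_id: str, df: pd.DataFrame) -> "ProbabilityTrajectory":
        cols = [ev.display_name for ev in EventLabel]
        return cls(embryo_id, df["hour"].to_numpy(), df[cols].to_numpy())


@dataclass(frozen=True)
class EventTimingConfig:
    """Per-event extraction mode and thresholds.

    Defaults: peak mode for Gastrula..Crawling, thresholds for the plateau
    events (Radula 0.6, Hatch 0.4, Dead 0.3), Pre-Gastrula excluded.
    """

    modes: dict[EventLabel, str] = field(default_factory=lambda: dict(_DEFAULT_MODES))
    thresholds: dict[EventLabel, float] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    smoothing_window: int = 0  # optional moving average; 0 = off (default)

    def __post_init__(self):
        for ev in EventLabel:
            if ev not in self.modes:
                raise ValueError(f"no extraction mode for {ev.display_name}")
            if self.modes[ev] not in ("peak", "threshold", "excluded"):
                raise ValueError(f"bad mode for {ev.display_name}: {self.modes[ev]!r}")
            if self.modes[ev] == "threshold":
                thr = self.thresholds.get(ev)
                if thr is None or not (0.0 < thr < 1.0):
                    raise ValueError(f"threshold for {ev.display_name} must lie in (0, 1)")

    def with_threshold(self, event: EventLabel, value: float) -> "EventTimingConfig":
        thr = dict(self.thresholds)
        thr[event] = value
        return replace(self, thresholds=thr)


_DEFAULT_MODES = {
    EventLabel.PRE_GASTRULA: "excluded",
    EventLabel.GASTRULA: "peak",
    EventLabel.TROCHOPHORE: "peak",
    EventLabel.VELIGER: "peak",
    EventLabel.EYE_SPOTS: "peak",
    EventLabel.HEART_BEAT: "peak",
    EventLabel.CRAWLING: "peak",
    EventLabel.RADULA: "threshold",
    EventLabel.HATCH: "threshold",
    EventLabel.DEAD: "threshold",
}
_DEFAULT_THRESHOLDS = {
    EventLabel.RADULA: 0.6,
    EventLabel.HATCH: 0.4,
    EventLabel.DEAD: 0.3,
}


@dataclass
class EventTimings:
    """Extracted onsets for one embryo; absent events are simply missing."""

    embryo_id: str
    onsets: dict[EventLabel, int]
    treatment: float | None = None

    def to_rows(self) -> list[dict]:
        return [
            {
                "embryo_id": self.embryo_id,
                "event": ev.display_name,
                "onset_hour": h,
                "treatment": self.treatment,
            }
            for ev, h in sorted(self.onsets.items(), key=lambda kv: kv[1])
        ]


def timings_to_frame(timings: list[EventTimings]) -> pd.DataFrame:
    rows = [r for t in timings for r in t.to_rows()]
    return pd.DataFrame(rows, columns=["embryo_id", "event", "onset_hour", "treatment"])


def predict_trajectory(
    model,
    timelapse: TimeLapse,
    size: int = 128,
    stride: int = 10,
    n_source_frames: int = 120,
    start_frame: int = 0,
    batch_size: int = 32,
) -> ProbabilityTrajectory:
    """Classify every imaged hour of one embryo, in hour order.

    Each clip is subsampled and standardised to the model's input shape;
    a shape mismatch raises an error naming the offending hour.
    """
    xs = []
    for hour, clip in zip(timelapse.hours, timelapse.clips):
        try:
            sub = subsample_clip(clip, start_frame, n_source_frames, stride)
            xs.append(standardize_clip(sub, size=size))
        except ValueError as exc:
            raise ValueError(f"hour {hour} of {timelapse.embryo_id}: {exc}") from exc
    x = np.stack(xs)
    probs = predict_proba(model, x, batch_size)
    return ProbabilityTrajectory(timelapse.embryo_id, np.array(timelapse.hours), probs)


def _maybe_smooth(col: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return col
    kernel = np.ones(window) / window
    return np.convolve(col, kernel, mode="same")


def extract_timing(
    traj: ProbabilityTrajectory,
    config: EventTimingConfig | None = None,
    treatment: float | None = None,
) -> EventTimings:
    """Apply the per-event peak/threshold rules to one trajectory.

    Peak mode returns the hour of the column's maximum (earliest on ties);
    threshold mode returns the earliest hour with probability strictly
    above the threshold, or no onset at all if it is never exceeded.
    Excluded events are never reported.  Hours are reported on the imaged
    grid; gaps are skipped, not interpolated.
    """
    config = config or EventTimingConfig()
    onsets: dict[EventLabel, int] = {}
    for ev in EventLabel:
        mode = config.modes[ev]
        if mode == "excluded":
            continue
        col = _maybe_smooth(traj.column(ev), config.smoothing_window)
        if mode == "peak":
            if np.all(col == 0):
                warnings.warn(
                    f"{traj.embryo_id}: all-zero trajectory for {ev.display_name}; "
                    "onset absent", stacklevel=2,
                )
                continue
            onsets[ev] = int(traj.hours[int(np.argmax(col))])
        else:  # threshold
            above = np.flatnonzero(col > config.thresholds[ev])
            if above.size:
                onsets[ev] = int(traj.hours[above[0]])
    return EventTimings(traj.embryo_id, onsets, treatment)


def calibrate_thresholds(
    trajectories: list[ProbabilityTrajectory],
    ground_truth: AnnotationTable,
    grid: list[float],
    config: EventTimingConfig | None = None,
) -> EventTimingConfig:
    """Choose per-event thresholds minimising mean absolute onset error.

    For every threshold-mode event, each grid value is evaluated against
    the annotated onsets over all trajectories; the value with the lowest
    mean absolute error wins, ties resolved to the lower threshold.  An
    event never predicted above any grid value is flagged with a warning
    and its default threshold is kept.
    """
    if not grid:
        raise ValueError("threshold grid must not be empty")
    config = config or EventTimingConfig()
    grid = sorted(grid)
    out = config
    for ev in EventLabel:
        if config.modes[ev] != "threshold":
            continue
        best: tuple[float, float] | None = None  # (mae, threshold)
        any_pred = False
        for thr in grid:
            errs = []
            for traj in trajectories:
                truth = ground_truth.onsets_for(traj.embryo_id).get(ev)
                if truth is None:
                    continue
                col = traj.column(ev)
                above = np.flatnonzero(col > thr)
                if above.size == 0:
                    continue
                any_pred = True
                errs.append(abs(int(traj.hours[above[0]]) - truth))
            if errs:
                mae = float(np.mean(errs))
                if best is None or mae < best[0]:
                    best = (mae, thr)
        if best is None:
            if not any_pred:
                warnings.warn(
                    f"{ev.display_name}: never predicted above any grid threshold",
                    stacklevel=2,
                )
            continue
        out = out.with_threshold(ev, best[1])
    return out
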