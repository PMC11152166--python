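"""Timing-extraction rules: peak, threshold, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from devevent.events import (
    EventTimingConfig,
    ProbabilityTrajectory,
    calibrate_thresholds,
    extract_timing,
)
from devevent.taxonomy import EventLabel, N_CLASSES
from devevent.video_io import AnnotationTable


def _traj(hours, columns: dict[EventLabel, list[float]], embryo="e"):
    """Build a trajectory with given per-event columns; the remainder of
    each row's mass goes to Pre-Gastrula so rows sum to one."""
    hours = np.asarray(hours)
    probs = np.zeros((len(hours), N_CLASSES))
    for ev, col in columns.items():
        probs[:, int(ev)] = col
    probs[:, 0] += 1.0 - probs.sum(axis=1)
    return ProbabilityTrajectory(embryo, hours, probs)


def test_default_timing_config_matches_protocol():
    cfg = EventTimingConfig()
    assert cfg.modes[EventLabel.PRE_GASTRULA] == "excluded"
    for ev in (EventLabel.GASTRULA, EventLabel.CRAWLING):
        assert cfg.modes[ev] == "peak"
    assert cfg.thresholds[EventLabel.RADULA] == 0.6
    assert cfg.thresholds[EventLabel.HATCH] == 0.4
    assert cfg.thresholds[EventLabel.DEAD] == 0.3


def test_peak_mode_returns_argmax_hour():
    traj = _traj([4, 5, 6], {EventLabel.GASTRULA: [0.1, 0.9, 0.2]})
    assert extract_timing(traj).onsets[EventLabel.GASTRULA] == 5


def test_peak_mode_tie_resolves_to_earliest_hour():
    traj = _traj([6, 7, 8, 9], {EventLabel.VELIGER: [0.1, 0.5, 0.2, 0.5]})
    assert extract_timing(traj).onsets[EventLabel.VELIGER] == 7


def test_threshold_mode_first_strict_crossing():
    traj = _traj([10, 11, 12, 13], {EventLabel.HATCH: [0.1, 0.39, 0.41, 0.8]})
    assert extract_timing(traj).onsets[EventLabel.HATCH] == 12
    # exactly-at-threshold never fires (strict inequality)
    flat = _traj([0, 1], {EventLabel.HATCH: [0.4, 0.4]})
    assert EventLabel.HATCH not in extract_timing(flat).onsets


def test_excluded_events_and_absent_events_not_reported():
    traj = _traj([0, 1, 2], {EventLabel.DEAD: [0.0, 0.0, 0.1]})
    timing = extract_timing(traj)
    assert EventLabel.PRE_GASTRULA not in timing.onsets
    assert EventLabel.DEAD not in timing.onsets  # never above 0.3


def test_peak_equals_brute_force_argmax_on_random_trajectories():
    rng = np.random.default_rng(11)
    cfg = EventTimingConfig()
    for _ in range(1000):
        n = int(rng.integers(2, 30))
        hours = np.cumsum(rng.integers(1, 3, size=n))
        raw = rng.random((n, N_CLASSES))
        probs = raw / raw.sum(axis=1, keepdims=True)
        traj = ProbabilityTrajectory("r", hours, probs)
        timing = extract_timing(traj, cfg)
        for ev in EventLabel:
            if cfg.modes[ev] != "peak":
                continue
            col = probs[:, int(ev)]
            best = None  # brute-force scan, earliest maximum
            for i in range(n):
                if best is None or col[i] > col[best]:
                    best = i
            assert timing.onsets[ev] == hours[best]


def test_threshold_onset_monotone_nondecreasing_in_threshold():
    rng = np.random.default_rng(5)
    hours = np.arange(25)
    col = np.clip(np.cumsum(rng.random(25)) / 14.0, 0, 0.95)
    traj = _traj(hours, {EventLabel.HATCH: col})
    prev = -1
    for thr in np.linspace(0.05, 0.9, 12):
        cfg = EventTimingConfig().with_threshold(EventLabel.HATCH, float(thr))
        onset = extract_timing(traj, cfg).onsets.get(EventLabel.HATCH)
        if onset is None:
            onset = 10**9  # absent counts as "later than any hour"
        assert onset >= prev
        prev = onset


def test_timing_reads_only_its_own_event_column():
    base = _traj([0, 1, 2, 3], {EventLabel.GASTRULA: [0.1, 0.8, 0.2, 0.1]})
    changed = _traj(
        [0, 1, 2, 3],
        {EventLabel.GASTRULA: [0.1, 0.8, 0.2, 0.1], EventLabel.RADULA: [0.0, 0.0, 0.7, 0.7]},
    )
    assert (
        extract_timing(base).onsets[EventLabel.GASTRULA]
        == extract_timing(changed).onsets[EventLabel.GASTRULA]
    )


def test_all_zero_peak_column_warns_and_reports_absent():
    traj = _traj([0, 1], {})
    with pytest.warns(UserWarning, match="all-zero"):
        timing = extract_timing(traj)
    assert EventLabel.GASTRULA not in timing.onsets


def test_trajectory_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        ProbabilityTrajectory("e", [0, 1], np.full((2, 10), 0.5))
    with pytest.raises(ValueError, match="strictly increasing"):
        _traj([1, 1], {})


def test_calibration_picks_lowest_threshold_on_step_trajectories():
    # perfect step at the true onset: every threshold below the step height
    # is optimal, so the lowest grid value wins the tie
    traj = _traj([0, 1, 2, 3], {EventLabel.HATCH: [0.0, 0.0, 0.9, 0.9]}, embryo="e1")
    truth = AnnotationTable.from_rows(
        [{"embryo_id": "e1", "event": "Hatch", "onset_hour": 2}]
    )
    cfg = calibrate_thresholds([traj], truth, grid=[0.2, 0.5, 0.8])
    assert cfg.thresholds[EventLabel.HATCH] == 0.2


def test_calibration_minimises_mae_against_exhaustive_grid():
    rng = np.random.default_rng(7)
    trajs, rows = [], []
    for i in range(6):
        onset = int(rng.integers(5, 15))
        hours = np.arange(20)
        col = 1 / (1 + np.exp(-(hours - onset - rng.normal(0, 0.8)))) * 0.9
        trajs.append(_traj(hours, {EventLabel.DEAD: col}, embryo=f"e{i}"))
        rows.append({"embryo_id": f"e{i}", "event": "Dead", "onset_hour": onset})
    truth = AnnotationTable.from_rows(rows)
    grid = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
    cfg = calibrate_thresholds(trajs, truth, grid)
    chosen = cfg.thresholds[EventLabel.DEAD]

    def mae(thr):
        errs = []
        for t, row in zip(trajs, rows):
            above = np.flatnonzero(t.column(EventLabel.DEAD) > thr)
            if above.size:
                errs.append(abs(int(t.hours[above[0]]) - row["onset_hour"]))
        return np.mean(errs) if errs else np.inf

    assert mae(chosen) == min(mae(t) for t in grid)


def test_calibration_empty_grid_rejected():
    with pytest.raises(ValueError, match="empty"):
        calibrate_thresholds([], AnnotationTable.from_rows(
            [{"embryo_id": "e", "event": "Hatch", "onset_hour": 1}]
        ), grid=[])


def test_trajectory_frame_roundtrip():
    traj = _traj([0, 2, 5], {EventLabel.HATCH: [0.1, 0.5, 0.9]})
    back = ProbabilityTrajectory.from_frame("e", traj.to_frame())
    np.testing.assert_allclose(back.probs, traj.probs)
    np.testing.assert_array_equal(back.hours, traj.hours)
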