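"""Generator contracts: determinism, motion oracles, labelling rule."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import ks_2samp

from devevent.synth import (
    MotifSpec,
    SyntheticSchedule,
    default_library,
    default_schedule,
    generate_embryo_series,
    make_temporal_only_pair,
    render_clip,
    thermal_rate,
    thermal_timings,
)
from devevent.taxonomy import CANONICAL_ORDER, EventLabel


def test_render_is_deterministic_in_motif_and_seed():
    motif = default_library()[EventLabel.HEART_BEAT]
    a = render_clip(motif, 30, 64, seed=9)
    b = render_clip(motif, 30, 64, seed=9)
    np.testing.assert_array_equal(a.frames, b.frames)
    c = render_clip(motif, 30, 64, seed=10)
    assert not np.array_equal(a.frames, c.frames)


def test_static_noiseless_motif_gives_identical_frames():
    motif = dataclasses.replace(default_library()[EventLabel.GASTRULA], noise_sd=0.0)
    clip = render_clip(motif, 12, 64, seed=0)
    for i in range(1, 12):
        np.testing.assert_array_equal(clip.frames[i], clip.frames[0])


def test_pulse_dominant_fourier_frequency_matches_spec():
    # FFT oracle: the mean-intensity time series of a pulsing motif has its
    # dominant discrete Fourier frequency at the motif's motion_frequency
    motif = dataclasses.replace(
        default_library()[EventLabel.HEART_BEAT], noise_sd=0.0, motion_frequency=2.0
    )
    fps, n = 30.0, 90
    clip = render_clip(motif, n, 64, seed=1, frame_rate=fps)
    series = clip.frames[..., 0].mean(axis=(1, 2)).astype(float)
    series -= series.mean()
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    dominant = freqs[np.abs(np.fft.rfft(series)).argmax()]
    assert dominant == pytest.approx(2.0, abs=freqs[1])


def test_invalid_motif_enums_rejected():
    with pytest.raises(ValueError, match="spatial_motif"):
        MotifSpec(EventLabel.GASTRULA, spatial_motif="starfish")
    with pytest.raises(ValueError, match="motion"):
        MotifSpec(EventLabel.GASTRULA, motion="teleport")
    with pytest.raises(ValueError, match="n_frames"):
        render_clip(default_library()[EventLabel.GASTRULA], 0)
    with pytest.raises(ValueError, match="size"):
        render_clip(default_library()[EventLabel.GASTRULA], 4, size=8)


def test_temporal_only_pair_first_frames_identical_later_frames_differ():
    a, b = make_temporal_only_pair(3)
    ca = render_clip(a, 30, 64, seed=7, frame_rate=3)
    cb = render_clip(b, 30, 64, seed=7, frame_rate=3)
    np.testing.assert_array_equal(ca.frames[0], cb.frames[0])
    assert np.abs(ca.frames[10].astype(int) - cb.frames[10].astype(int)).mean() > 0


def test_temporal_only_pair_first_frame_distributions_match():
    # KS test over matched-seed clips: first-frame pixel distributions of the
    # static and moving motif are statistically identical
    a, b = make_temporal_only_pair(0)
    fa, fb = [], []
    for i in range(100):
        fa.append(render_clip(a, 2, 32, seed=i).frames[0].mean())
        fb.append(render_clip(b, 2, 32, seed=1000 + i).frames[0].mean())
    assert ks_2samp(fa, fb).pvalue > 0.05


def test_series_follows_previous_event_labelling_rule():
    sched = SyntheticSchedule(
        "e", {EventLabel.GASTRULA: 5, EventLabel.HATCH: 20}, total_hours=25,
        frame_rate=2, clip_seconds=1, allow_heterochrony=True,
    )
    assert [sched.label_at(h) for h in (0, 4)] == [EventLabel.PRE_GASTRULA] * 2
    assert all(sched.label_at(h) == EventLabel.GASTRULA for h in range(5, 20))
    assert all(sched.label_at(h) == EventLabel.HATCH for h in range(20, 26))
    # the label of the clip at an event's onset hour is that event
    assert sched.label_at(5) == EventLabel.GASTRULA


def test_series_regeneration_is_identical_and_annotations_match():
    rng = np.random.default_rng(4)
    sched = default_schedule("e7", rng, frame_rate=2, clip_seconds=2)
    tl1, ann1 = generate_embryo_series(sched, seed=11, size=32)
    tl2, ann2 = generate_embryo_series(sched, seed=11, size=32)
    assert tl1.hours == list(range(sched.total_hours + 1))
    for c1, c2 in zip(tl1.clips, tl2.clips):
        np.testing.assert_array_equal(c1.frames, c2.frames)
    assert ann1.df.equals(ann2.df)
    assert ann1.onsets_for("e7") == sched.onsets


def test_schedule_rejects_disordered_onsets_unless_heterochrony():
    onsets = {EventLabel.GASTRULA: 10, EventLabel.TROCHOPHORE: 5}
    with pytest.raises(ValueError, match="canonical"):
        SyntheticSchedule("e", onsets, total_hours=12)
    ok = SyntheticSchedule("e", onsets, total_hours=12, allow_heterochrony=True)
    assert ok.label_at(7) == EventLabel.TROCHOPHORE


def test_thermal_timings_build_in_lower_late_t_opt():
    timings = thermal_timings(n_per_treatment=5, seed=0)
    assert len(timings) == 5 * 8
    assert all(t.treatment is not None for t in timings)
    # the built-in rate model peaks exactly at the configured optima
    assert thermal_rate(27.5, 27.5) == 1.0
    assert thermal_rate(32.5, 25.0) < thermal_rate(32.5, 27.5)


def test_every_event_has_exactly_one_motif():
    lib = default_library()
    assert set(lib) == set(CANONICAL_ORDER)
    for ev, motif in lib.items():
        assert motif.event_label == ev
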