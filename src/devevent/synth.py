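"""Synthetic embryo time-lapse generator with known event schedules.

Renders hourly grayscale clips of an egg-bounded "embryo" whose appearance
and motion change at scheduled developmental-event onsets, so every
downstream stage (I/O, augmentation, training, timing extraction, thermal
summaries) is testable without external data.

Each event class maps to one :class:`MotifSpec`: a spatial motif (a soft
blob, a blob with spots, a shelled blob, an empty egg capsule, or a
speckled decaying texture) plus a deterministic parametric motion
(sinusoidal intensity pulse, rigid rotation, oscillating translation, or
slow drift).  Motions are analytic functions of the frame timestamp, so a
Fourier or displacement oracle can verify them, and a clip is a pure
function of ``(motif, seed)`` — bit-identical on regeneration.

These motifs are test proxies with distinguishable spatio-temporal
signatures, not renderings of real embryo morphologies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .taxonomy import CANONICAL_ORDER, EventLabel
from .video_io import AnnotationTable, Clip, TimeLapse

SPATIAL_MOTIFS = ("blob", "blob_with_spots", "shelled_blob", "empty_capsule", "speckled_decay")
MOTIONS = ("none", "pulse", "rotate", "translate", "drift")

_BACKGROUND = 30.0
_CAPSULE_INTENSITY = 70.0
_CAPSULE_RADIUS = 0.82  # in units of the half frame


@dataclass(frozen=True)
class MotifSpec:
    """Appearance + motion signature rendered for one event class.

    ``motion_amplitude`` is in pixels for rigid motions (rotate uses it as
    the spot orbit is fixed; translate/drift as displacement) and as a
    fractional intensity change for ``pulse``.  ``motion_frequency`` is in
    cycles per second of footage; ``noise_sd`` is additive Gaussian noise
    in 8-bit grayscale units, clipped to [0, 255].
    """

    event_label: EventLabel
    spatial_motif: str = "blob"
    motion: str = "none"
    motion_amplitude: float = 0.0
    motion_frequency: float = 0.0
    noise_sd: float = 0.0
    size_frac: float = 0.35  # embryo radius / half frame size
    intensity: float = 150.0  # peak embryo grayscale above background
    decoration_strength: float = 1.0  # contrast of spots/shell/speckles

    def __post_init__(self):
        if self.spatial_motif not in SPATIAL_MOTIFS:
            raise ValueError(f"unknown spatial_motif: {self.spatial_motif!r}")
        if self.motion not in MOTIONS:
            raise ValueError(f"unknown motion: {self.motion!r}")
        if self.motion_frequency < 0:
            raise ValueError("motion_frequency must be >= 0")


MotifLibrary = dict[EventLabel, MotifSpec]


def default_library(noise_sd: float = 2.0) -> MotifLibrary:
    """One distinguishable motif per event class.

    Spatial size/brightness and motion jointly separate the ten classes;
    morphological events are static or slowly moving, physiological events
    (heart beat, radula, crawling) are defined mainly by motion.
    """
    lib = {
        EventLabel.PRE_GASTRULA: MotifSpec(
            EventLabel.PRE_GASTRULA, "blob", "none", size_frac=0.18, intensity=90, noise_sd=noise_sd
        ),
        EventLabel.GASTRULA: MotifSpec(
            EventLabel.GASTRULA, "blob", "none", size_frac=0.34, intensity=120, noise_sd=noise_sd
        ),
        EventLabel.TROCHOPHORE: MotifSpec(
            EventLabel.TROCHOPHORE, "blob", "rotate", motion_amplitude=4, motion_frequency=0.5,
            size_frac=0.30, intensity=160, noise_sd=noise_sd,
        ),
        EventLabel.VELIGER: MotifSpec(
            EventLabel.VELIGER, "shelled_blob", "rotate", motion_amplitude=4, motion_frequency=0.25,
            size_frac=0.38, intensity=150, noise_sd=noise_sd,
        ),
        EventLabel.EYE_SPOTS: MotifSpec(
            EventLabel.EYE_SPOTS, "blob_with_spots", "none", size_frac=0.40, intensity=150,
            noise_sd=noise_sd,
        ),
        EventLabel.HEART_BEAT: MotifSpec(
            EventLabel.HEART_BEAT, "blob_with_spots", "pulse", motion_amplitude=0.35,
            motion_frequency=2.0, size_frac=0.42, intensity=160, noise_sd=noise_sd,
        ),
        EventLabel.CRAWLING: MotifSpec(
            EventLabel.CRAWLING, "blob", "translate", motion_amplitude=6, motion_frequency=0.4,
            size_frac=0.45, intensity=180, noise_sd=noise_sd,
        ),
        EventLabel.RADULA: MotifSpec(
            EventLabel.RADULA, "shelled_blob", "pulse", motion_amplitude=0.5,
            motion_frequency=4.0, size_frac=0.48, intensity=170, noise_sd=noise_sd,
        ),
        EventLabel.HATCH: MotifSpec(
            EventLabel.HATCH, "empty_capsule", "none", size_frac=0.4, intensity=60,
            noise_sd=noise_sd,
        ),
        EventLabel.DEAD: MotifSpec(
            EventLabel.DEAD, "speckled_decay", "drift", motion_amplitude=1.5,
            motion_frequency=0.1, size_frac=0.5, intensity=110, noise_sd=noise_sd,
        ),
    }
    assert set(lib) == set(EventLabel)
    return lib


@dataclass(frozen=True)
class SyntheticSchedule:
    """Known event-onset schedule for one synthetic embryo."""

    embryo_id: str
    onsets: dict[EventLabel, int]
    total_hours: int
    frame_rate: float = 30.0
    clip_seconds: float = 20.0
    allow_heterochrony: bool = False

    def __post_init__(self):
        if not self.onsets:
            raise ValueError("schedule must contain at least one onset")
        for ev, h in self.onsets.items():
            if h < 0:
                raise ValueError(f"onset hour for {ev.display_name} must be >= 0")
        if self.total_hours < max(self.onsets.values()):
            raise ValueError("total_hours must cover the latest onset")
        if not self.allow_heterochrony:
            ordered = [self.onsets[ev] for ev in CANONICAL_ORDER if ev in self.onsets]
            if any(b <= a for a, b in zip(ordered, ordered[1:])):
                raise ValueError(
                    "onsets must be strictly increasing along the canonical event order "
                    "(pass allow_heterochrony=True for explicit heterochronic schedules)"
                )

    def label_at(self, hour: int) -> EventLabel:
        """The annotation rule: the previous event holds until the next occurs."""
        best: tuple[int, int] | None = None
        label = EventLabel.PRE_GASTRULA
        for ev, onset in self.onsets.items():
            if onset <= hour:
                key = (onset, int(ev))
                if best is None or key > best:
                    best, label = key, ev
        return label


def render_clip(
    motif: MotifSpec,
    n_frames: int,
    size: int = 64,
    seed: int = 0,
    frame_rate: float = 30.0,
) -> Clip:
    """Render one clip of ``n_frames`` frames at ``size x size`` pixels.

    Deterministic: identical ``(motif, seed)`` give bit-identical clips.
    At t=0 every motion is at its neutral phase, so clips that differ only
    in motion share an identical first frame.
    """
    rng = np.random.default_rng(seed)
    frames = _render_fields(motif, n_frames, size, rng, frame_rate)
    return Clip(_quantize(frames, motif.noise_sd, rng))


def _quantize(frames: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return np.clip(frames, 0, 255).astype(np.uint8)[..., None]


def _render_fields(
    motif: MotifSpec,
    n_frames: int,
    size: int,
    rng: np.random.Generator,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Noiseless float frames (n_frames, size, size); pure function of the
    motif, the rng state (speckle placement only) and the timestamps."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if size < 16:
        raise ValueError("size must be >= 16")
    t = np.arange(n_frames, dtype=np.float64) / frame_rate
    ax = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    r_cap = np.sqrt(xx**2 + yy**2)

    base = np.full((size, size), _BACKGROUND, dtype=np.float64)
    ring = np.exp(-((r_cap - _CAPSULE_RADIUS) ** 2) / (2 * 0.03**2))
    base += _CAPSULE_INTENSITY * ring

    # per-frame centre displacement (in normalised units) and phase
    two_pi_ft = 2.0 * np.pi * motif.motion_frequency * t
    dx = np.zeros(n_frames)
    dy = np.zeros(n_frames)
    scale = np.ones(n_frames)
    angle = np.zeros(n_frames)
    amp_px = motif.motion_amplitude / (size / 2.0)
    if motif.motion == "pulse":
        scale = 1.0 + motif.motion_amplitude * np.sin(two_pi_ft)
    elif motif.motion == "rotate":
        angle = two_pi_ft
    elif motif.motion == "translate":
        dx = amp_px * np.sin(two_pi_ft)
        dy = amp_px * 0.5 * np.sin(2.0 * two_pi_ft)
    elif motif.motion == "drift":
        dx = amp_px * motif.motion_frequency * t
        dy = -0.5 * amp_px * motif.motion_frequency * t

    # speckle positions are part of the deterministic (motif, seed) state
    if motif.spatial_motif == "speckled_decay":
        n_speck = 60
        theta = rng.uniform(0, 2 * np.pi, n_speck)
        rad = motif.size_frac * np.sqrt(rng.uniform(0, 1, n_speck)) * _CAPSULE_RADIUS
        sx, sy = rad * np.cos(theta), rad * np.sin(theta)

    frames = np.empty((n_frames, size, size), dtype=np.float64)
    sf = motif.size_frac
    for i in range(n_frames):
        img = base.copy()
        cx, cy = dx[i], dy[i]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        if motif.spatial_motif in ("blob", "blob_with_spots", "shelled_blob"):
            body = motif.intensity * np.exp(-((r2 / sf**2) ** 2))
            img += scale[i] * body
        deco = motif.decoration_strength
        if motif.spatial_motif == "blob_with_spots":
            for k, (ox, oy) in enumerate(((-0.4, -0.35), (0.4, -0.35), (0.0, 0.45))):
                a = angle[i] + k  # fixed per-spot phase offset
                px = cx + sf * (ox * np.cos(a) - oy * np.sin(a))
                py = cy + sf * (ox * np.sin(a) + oy * np.cos(a))
                spot = np.exp(-(((xx - px) ** 2 + (yy - py) ** 2) / (0.06 * sf) ** 2))
                img -= deco * scale[i] * 0.8 * motif.intensity * spot
        if motif.spatial_motif == "shelled_blob":
            shell_angle = np.arctan2(yy - cy, xx - cx) - angle[i]
            crescent = np.exp(-((np.sqrt(r2) - sf) ** 2) / (2 * 0.05**2))
            crescent *= (np.cos(shell_angle) + 1.0) / 2.0
            img += deco * scale[i] * 0.9 * motif.intensity * crescent
        if motif.spatial_motif == "speckled_decay":
            interior = motif.intensity * 0.35 * np.exp(-((r_cap / (sf * 1.6)) ** 4))
            img += interior
            for px, py in zip(sx, sy):
                spot = np.exp(-(((xx - (px + cx)) ** 2 + (yy - (py + cy)) ** 2) / 0.002))
                img += deco * motif.intensity * 0.6 * spot
        frames[i] = img

    return frames


def clip_seed(seed: int, embryo_id: str, hour: int) -> int:
    """Stable per-(embryo, hour) seed derived from the run seed."""
    import zlib

    h = zlib.crc32(embryo_id.encode()) & 0xFFFF
    return int(np.random.SeedSequence([seed, h, hour]).generate_state(1)[0] % (2**31))


#: Appearance every aged signature relaxes toward: a featureless mid-size blob.
_NEUTRAL_SIZE_FRAC = 0.36
_NEUTRAL_INTENSITY = 135.0

#: Terminal states whose appearance does not fade (a hatched egg stays
#: hatched; a dead embryo stays dead).
_TERMINAL_EVENTS = (EventLabel.HATCH, EventLabel.DEAD)


def aged_motif(motif: MotifSpec, age_hours: float, fade_tau: float) -> MotifSpec:
    """The motif as it looks ``age_hours`` after the event's onset.

    An event's distinguishing signature — its motion amplitude, its spots,
    shell or speckles, and its deviation from a neutral blob in size and
    brightness — is strongest at onset and decays exponentially with age
    (time constant ``fade_tau`` hours).  Terminal events never fade.
    """
    if fade_tau <= 0 or age_hours <= 0 or motif.event_label in _TERMINAL_EVENTS:
        return motif
    k = float(np.exp(-age_hours / fade_tau))
    return dataclasses.replace(
        motif,
        motion_amplitude=motif.motion_amplitude * k,
        decoration_strength=motif.decoration_strength * k,
        size_frac=_NEUTRAL_SIZE_FRAC + (motif.size_frac - _NEUTRAL_SIZE_FRAC) * k,
        intensity=_NEUTRAL_INTENSITY + (motif.intensity - _NEUTRAL_INTENSITY) * k,
    )


def generate_embryo_series(
    schedule: SyntheticSchedule,
    library: MotifLibrary | None = None,
    seed: int = 0,
    size: int = 64,
    fade_tau: float = 1.5,
) -> tuple[TimeLapse, AnnotationTable]:
    """Render one clip per hour 0..total_hours and the matching annotations.

    The clip at hour ``h`` is rendered from the motif of the latest event
    with onset <= h (Pre-Gastrula before the first onset) — the labelling
    rule that a sample keeps the previous event's label until the next
    event occurs.

    Development is most characteristic right at an event: the motif's
    signature is rendered at full strength at its onset hour and fades
    toward a neutral appearance as the event ages (see :func:`aged_motif`,
    time constant ``fade_tau`` hours; 0 disables fading).  This is what
    makes a classifier's probability trajectory peak at the onset rather
    than drifting across the event's span.
    """
    library = library or default_library()
    n_frames = int(round(schedule.frame_rate * schedule.clip_seconds))
    hours = list(range(schedule.total_hours + 1))
    clips = []
    for h in hours:
        label = schedule.label_at(h)
        onset_cur = schedule.onsets.get(label, 0)
        motif = aged_motif(library[label], h - onset_cur, fade_tau)
        rng = np.random.default_rng(clip_seed(seed, schedule.embryo_id, h))
        fields = _render_fields(motif, n_frames, size, rng, schedule.frame_rate)
        clip = Clip(_quantize(fields, motif.noise_sd, rng))
        clip.source_id = f"{schedule.embryo_id}:h{h}"
        clips.append(clip)
    rows = [
        {"embryo_id": schedule.embryo_id, "event": ev.display_name, "onset_hour": onset}
        for ev, onset in sorted(schedule.onsets.items(), key=lambda kv: kv[1])
    ]
    return TimeLapse(schedule.embryo_id, hours, clips), AnnotationTable.from_rows(rows)


def make_temporal_only_pair(seed: int = 0) -> tuple[MotifSpec, MotifSpec]:
    """Two motifs identical in every static respect, differing only in motion.

    Rendered with matched seeds, their first frames are bit-identical
    (pulse phase is neutral at t=0) while later frames differ — a dataset
    on which any first-frame-only classifier is at chance by construction.
    """
    rng = np.random.default_rng(seed)
    sf = float(rng.uniform(0.3, 0.4))
    inten = float(rng.uniform(130, 170))
    static = MotifSpec(
        EventLabel.GASTRULA, "blob", "none", size_frac=sf, intensity=inten, noise_sd=2.0
    )
    moving = dataclasses.replace(
        static,
        event_label=EventLabel.HEART_BEAT,
        motion="pulse",
        motion_amplitude=0.4,
        motion_frequency=2.0,
    )
    return static, moving


#: Chronic assay temperatures (°C) of the thermal-plasticity design.
ASSAY_TEMPERATURES = (15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0, 32.5)

#: Baseline mean onset hours at the thermal optimum, per event.
_BASE_ONSETS = {
    EventLabel.GASTRULA: 6.0,
    EventLabel.TROCHOPHORE: 22.0,
    EventLabel.VELIGER: 45.0,
    EventLabel.EYE_SPOTS: 70.0,
    EventLabel.HEART_BEAT: 85.0,
    EventLabel.CRAWLING: 100.0,
    EventLabel.RADULA: 115.0,
    EventLabel.HATCH: 150.0,
}

#: Events treated as "late" for the built-in T_opt reduction.
_LATE_EVENTS = (EventLabel.CRAWLING, EventLabel.RADULA, EventLabel.HATCH)


def thermal_rate(temperature: float, t_opt: float, width: float = 12.0) -> float:
    """Relative developmental rate: a quadratic peaking at ``t_opt``.

    Normalised to 1 at the optimum and floored at 0.15 so onsets stay
    finite at the assay extremes.
    """
    return max(0.15, 1.0 - ((temperature - t_opt) / width) ** 2)


def thermal_timings(
    n_per_treatment: int = 20,
    temperatures: tuple[float, ...] = ASSAY_TEMPERATURES,
    seed: int = 0,
    t_opt_early: float = 27.5,
    t_opt_late: float = 25.0,
    cv: float = 0.05,
):
    """Synthetic per-embryo event timings across chronic temperatures.

    Emulates the thermal-plasticity design: warming accelerates every
    event, but the built-in optimum temperature is lower for late events
    (``t_opt_late`` < ``t_opt_early``) — the ground truth against which
    T_opt recovery is tested.  Onsets are Normal around the treatment mean
    with coefficient of variation ``cv``.

    Returns a list of :class:`devevent.events.EventTimings`.
    """
    from .events import EventTimings  # deferred: events imports train

    rng = np.random.default_rng(seed)
    out = []
    for temp in temperatures:
        for i in range(n_per_treatment):
            onsets: dict[EventLabel, int] = {}
            for ev, base in _BASE_ONSETS.items():
                t_opt = t_opt_late if ev in _LATE_EVENTS else t_opt_early
                mean = base / thermal_rate(temp, t_opt)
                onsets[ev] = max(1, int(round(rng.normal(mean, cv * mean))))
            out.append(
                EventTimings(f"T{temp:g}_e{i}", onsets, treatment=float(temp))
            )
    return out


def default_schedule(
    embryo_id: str,
    rng: np.random.Generator,
    events: tuple[EventLabel, ...] = (
        EventLabel.GASTRULA,
        EventLabel.TROCHOPHORE,
        EventLabel.VELIGER,
        EventLabel.EYE_SPOTS,
        EventLabel.HEART_BEAT,
        EventLabel.CRAWLING,
        EventLabel.RADULA,
        EventLabel.HATCH,
    ),
    mean_gap: float = 3.0,
    jitter: float = 1.0,
    frame_rate: float = 30.0,
    clip_seconds: float = 20.0,
) -> SyntheticSchedule:
    """Draw a plausible strictly-ordered schedule with jittered gaps."""
    onsets: dict[EventLabel, int] = {}
    h = 0
    for ev in events:
        gap = max(1, int(round(rng.normal(mean_gap, jitter))))
        h += gap
        onsets[ev] = h
    return SyntheticSchedule(
        embryo_id, onsets, total_hours=h + 2, frame_rate=frame_rate, clip_seconds=clip_seconds
    )
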