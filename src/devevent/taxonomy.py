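"""Canonical developmental-event taxonomy.

Ten functional events spanning embryonic development of an egg-bound
gastropod, from gastrulation through hatching (or death).  The integer
codes are the class indices the classifier predicts, and the listed order
is the canonical developmental order used everywhere downstream
(annotation, scheduling, timing extraction, plotting).
"""

from __future__ import annotations

import enum


class EventLabel(enum.IntEnum):
    """Developmental event classes in canonical order (codes 0-9)."""

    PRE_GASTRULA = 0
    GASTRULA = 1
    TROCHOPHORE = 2
    VELIGER = 3
    EYE_SPOTS = 4
    HEART_BEAT = 5
    CRAWLING = 6
    RADULA = 7
    HATCH = 8
    DEAD = 9

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "EventLabel":
        """Resolve a label from its display name, enum name, or code."""
        key = name.strip()
        for ev, disp in _DISPLAY_NAMES.items():
            if key.lower() == disp.lower():
                return ev
        try:
            return cls[key.upper().replace(" ", "_").replace("-", "_")]
        except KeyError:
            pass
        try:
            return cls(int(key))
        except ValueError:
            raise ValueError(f"unknown event label: {name!r}") from None


_DISPLAY_NAMES = {
    EventLabel.PRE_GASTRULA: "Pre-Gastrula",
    EventLabel.GASTRULA: "Gastrula",
    EventLabel.TROCHOPHORE: "Trochophore",
    EventLabel.VELIGER: "Veliger",
    EventLabel.EYE_SPOTS: "Eye spots",
    EventLabel.HEART_BEAT: "Heart beat",
    EventLabel.CRAWLING: "Crawling",
    EventLabel.RADULA: "Radula",
    EventLabel.HATCH: "Hatch",
    EventLabel.DEAD: "Dead",
}

#: Events in canonical developmental order.
CANONICAL_ORDER: tuple[EventLabel, ...] = tuple(EventLabel)

N_CLASSES = len(EventLabel)
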