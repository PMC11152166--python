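"""Treatment-level summaries, thermal-performance curves and projections.

Given extracted event timings grouped by temperature treatment, this
module computes the mean +/- s.d. onset per (temperature, event), the
developmental rate (reciprocal of mean onset, per hour) and its optimum
temperature T_opt, and 2D projections (PCA or UMAP) of triplet-loss
embeddings coloured by event and by relative developmental time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTimings, timings_to_frame
from .taxonomy import EventLabel


def summarize_treatments(timings: list[EventTimings]) -> pd.DataFrame:
    """Mean/s.d./n of onset hours per (temperature, event).

    Pre-Gastrula never appears (it marks development before the first
    event, not an event).  Embryos lacking an event contribute nothing to
    that event's row (n shrinks; no imputation); single-embryo cells
    report s.d. 0 and are flagged.
    """
    if not timings:
        raise ValueError("no timings to summarise")
    df = timings_to_frame(timings)
    df = df[df["event"] != EventLabel.PRE_GASTRULA.display_name]
    grouped = (
        df.groupby(["treatment", "event"], dropna=False)["onset_hour"]
        .agg(mean_onset_hour="mean", sd_onset_hour=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["sd_onset_hour"] = grouped["sd_onset_hour"].fillna(0.0)
    grouped["single_embryo"] = grouped["n"] == 1
    order = {ev.display_name: int(ev) for ev in EventLabel}
    grouped["event_code"] = grouped["event"].map(order)
    return grouped.sort_values(["treatment", "event_code"]).drop(columns="event_code").reset_index(drop=True)


@dataclass
class ThermalCurve:
    """Developmental rate (1 / mean onset hour) across assay temperatures."""

    event: EventLabel
    temperatures: np.ndarray
    rates: np.ndarray  # per hour
    t_opt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event": self.event.display_name,
                "temperature": self.temperatures,
                "rate_per_hour": self.rates,
                "t_opt": self.t_opt,
            }
        )


def thermal_curve(summaries: pd.DataFrame, event: EventLabel | str) -> ThermalCurve:
    """Rate curve and T_opt for one event from a treatment summary table.

    T_opt is the assayed temperature with the highest mean rate, reported
    on the assay grid (no curve fitting); ties resolve to the lower
    temperature.
    """
    name = event.display_name if isinstance(event, EventLabel) else event
    sub = summaries[summaries["event"] == name].sort_values("treatment")
    if len(sub) < 2:
        raise ValueError(f"need >= 2 temperatures for a thermal curve ({name})")
    temps = sub["treatment"].to_numpy(dtype=float)
    means = sub["mean_onset_hour"].to_numpy(dtype=float)
    if np.any(means <= 0):
        raise ValueError("mean onset hours must be positive to form rates")
    rates = 1.0 / means
    t_opt = float(temps[int(np.argmax(rates))])  # argmax takes the first (lowest T) on ties
    return ThermalCurve(EventLabel.from_name(name), temps, rates, t_opt)


def relative_time(hours, terminal_hour: float | None) -> np.ndarray:
    """Developmental time normalised to the terminal event (hatch or death).

    ``hour / terminal_hour`` clamped to [0, 1]; embryos without a terminal
    event are excluded with a warning (returns an empty array).
    """
    hours = np.asarray(hours, dtype=float)
    if terminal_hour is None or terminal_hour <= 0:
        warnings.warn("no terminal event (hatch/death); samples excluded", stacklevel=2)
        return np.empty(0)
    return np.clip(hours / float(terminal_hour), 0.0, 1.0)


def terminal_hour_of(timings: EventTimings) -> float | None:
    """Hour of hatch or death, whichever is recorded (hatch preferred)."""
    for ev in (EventLabel.HATCH, EventLabel.DEAD):
        if ev in timings.onsets:
            return float(timings.onsets[ev])
    return None


def project_embeddings(
    embeddings: np.ndarray,
    method: str = "linear_pca",
    labels: np.ndarray | None = None,
    rel_time: np.ndarray | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Project unit-norm embeddings to 2D.

    ``linear_pca`` returns the top-2 principal components;
    ``nonlinear_neighbor`` runs UMAP with the pinned defaults
    (n_neighbors=15, n_components=2, metric=euclidean, min_dist=0.1),
    seed-controlled.  Labels and relative times pass through unaltered.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2:
        raise ValueError("embeddings must be (n_samples, dim)")
    if method == "linear_pca":
        from sklearn.decomposition import PCA

        xy = PCA(n_components=2, random_state=seed).fit_transform(emb)
    elif method == "nonlinear_neighbor":
        if emb.shape[0] <= n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={n_neighbors} samples; got {emb.shape[0]}"
            )
        import umap

        xy = umap.UMAP(
            n_neighbors=n_neighbors,
            n_components=2,
            metric="euclidean",
            min_dist=min_dist,
            random_state=seed,
        ).fit_transform(emb)
    else:
        raise ValueError(f"unknown projection method: {method!r}")
    out = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})
    if labels is not None:
        if len(labels) != len(out):
            raise ValueError("labels length mismatch")
        out["event"] = [EventLabel(int(l)).display_name for l in labels]
    if rel_time is not None:
        if len(rel_time) != len(out):
            raise ValueError("rel_time length mismatch")
        out["relative_time"] = np.asarray(rel_time, dtype=float)
    return out
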