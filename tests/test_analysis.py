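"""Treatment summaries, thermal curves and embedding projections."""

import numpy as np
import pandas as pd
import pytest

from devevent.analysis import (
    project_embeddings,
    relative_time,
    summarize_treatments,
    terminal_hour_of,
    thermal_curve,
)
from devevent.events import EventTimings
from devevent.taxonomy import EventLabel


def _timings(mu=100.0, sigma=5.0, n=50, treatment=20.0, seed=0, event=EventLabel.HATCH):
    rng = np.random.default_rng(seed)
    return [
        EventTimings(f"e{i}", {event: int(round(rng.normal(mu, sigma)))}, treatment)
        for i in range(n)
    ]


def test_summary_recovers_generating_distribution():
    summary = summarize_treatments(_timings())
    row = summary.iloc[0]
    assert row["event"] == "Hatch" and row["n"] == 50
    assert abs(row["mean_onset_hour"] - 100) < 2
    assert abs(row["sd_onset_hour"] - 5) < 1.5


def test_summary_excludes_pre_gastrula_and_flags_single_embryo():
    tms = [
        EventTimings("a", {EventLabel.PRE_GASTRULA: 0, EventLabel.HATCH: 10}, 15.0),
        EventTimings("b", {EventLabel.GASTRULA: 3}, 15.0),
    ]
    summary = summarize_treatments(tms)
    assert "Pre-Gastrula" not in set(summary["event"])
    hatch = summary[summary["event"] == "Hatch"].iloc[0]
    assert hatch["n"] == 1 and hatch["sd_onset_hour"] == 0.0 and hatch["single_embryo"]


def test_missing_events_shrink_n_without_imputation():
    tms = _timings(n=10) + [EventTimings("x", {EventLabel.GASTRULA: 5}, 20.0)]
    summary = summarize_treatments(tms)
    assert summary[summary["event"] == "Hatch"].iloc[0]["n"] == 10


def test_thermal_curve_rates_and_t_opt():
    summary = pd.DataFrame(
        {
            "treatment": [15.0, 25.0],
            "event": ["Hatch", "Hatch"],
            "mean_onset_hour": [200.0, 100.0],
            "sd_onset_hour": [5.0, 5.0],
            "n": [10, 10],
        }
    )
    curve = thermal_curve(summary, EventLabel.HATCH)
    np.testing.assert_allclose(curve.rates, [0.005, 0.01])
    assert curve.t_opt == 25.0


def test_thermal_curve_tie_goes_to_lower_temperature():
    summary = pd.DataFrame(
        {
            "treatment": [15.0, 20.0, 25.0],
            "event": ["Hatch"] * 3,
            "mean_onset_hour": [100.0, 100.0, 100.0],
            "sd_onset_hour": [1.0] * 3,
            "n": [5, 5, 5],
        }
    )
    assert thermal_curve(summary, "Hatch").t_opt == 15.0


def test_thermal_curve_invariant_to_embryo_order_and_duplication():
    tms = _timings(n=20, treatment=15.0, seed=1) + _timings(
        mu=60, n=20, treatment=25.0, seed=2
    )
    c1 = thermal_curve(summarize_treatments(tms), EventLabel.HATCH)
    c2 = thermal_curve(summarize_treatments(tms[::-1]), EventLabel.HATCH)
    np.testing.assert_allclose(c1.rates, c2.rates)
    assert c1.t_opt == c2.t_opt


def test_relative_time_normalisation_and_monotonicity():
    np.testing.assert_allclose(relative_time([0, 50, 100], 100.0), [0.0, 0.5, 1.0])
    out = relative_time(np.arange(0, 120, 10), 100.0)
    assert np.all(np.diff(out) >= 0)
    assert out.max() == 1.0  # clamped beyond the terminal hour
    with pytest.warns(UserWarning, match="terminal"):
        assert relative_time([0, 1], None).size == 0


def test_terminal_hour_prefers_hatch_over_death():
    t = EventTimings("e", {EventLabel.HATCH: 90, EventLabel.DEAD: 95})
    assert terminal_hour_of(t) == 90.0
    assert terminal_hour_of(EventTimings("e", {EventLabel.GASTRULA: 3})) is None


def test_pca_projection_recovers_planar_structure():
    rng = np.random.default_rng(3)
    basis = np.linalg.qr(rng.normal(size=(8, 2)))[0]
    coords = rng.normal(size=(40, 2))
    emb = coords @ basis.T  # exactly rank-2 data in 8 dimensions
    proj = project_embeddings(emb, "linear_pca")
    # distances are preserved exactly for data lying in a 2D subspace
    d_orig = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    xy = proj[["x", "y"]].to_numpy()
    d_proj = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)


def test_pca_projection_invariant_to_sample_order_up_to_sign():
    rng = np.random.default_rng(4)
    emb = rng.normal(size=(30, 6))
    perm = rng.permutation(30)
    a = project_embeddings(emb, "linear_pca")[["x", "y"]].to_numpy()
    b = project_embeddings(emb[perm], "linear_pca")[["x", "y"]].to_numpy()
    for k in range(2):
        assert np.allclose(a[perm, k], b[:, k], atol=1e-8) or np.allclose(
            a[perm, k], -b[:, k], atol=1e-8
        )


def test_projection_preserves_labels_and_counts():
    rng = np.random.default_rng(5)
    emb = rng.normal(size=(25, 4))
    labels = rng.integers(0, 3, 25)
    rel = rng.random(25)
    proj = project_embeddings(emb, "linear_pca", labels=labels, rel_time=rel)
    assert len(proj) == 25
    assert list(proj["event"]) == [EventLabel(int(l)).display_name for l in labels]
    np.testing.assert_allclose(proj["relative_time"], rel)


def test_umap_projection_requires_enough_samples():
    with pytest.raises(ValueError, match="n_neighbors"):
        project_embeddings(np.zeros((10, 4)), "nonlinear_neighbor", n_neighbors=15)
    with pytest.raises(ValueError, match="unknown projection"):
        project_embeddings(np.zeros((10, 4)), "tsne")
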