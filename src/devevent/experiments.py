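"""Reference experiments on the synthetic generator, at CPU scale.

Each function runs one self-contained study — data generation, training,
evaluation — and returns a plain dict of the quantities it measured.  The
problem sizes are deliberately small (tiny model specs on 32x32 clips,
tens to hundreds of samples, three repeat seeds) so the full battery runs
on a single CPU in minutes; the properties they probe are qualitative
(temporal information matters, onsets are recoverable, embeddings
separate, stride effects are null, T_opt shifts are detectable), not the
accuracies of a GPU-scale run on real video.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import silhouette_score

from .analysis import project_embeddings, summarize_treatments, thermal_curve
from .augment import balance_classes
from .events import extract_timing, predict_trajectory
from .model import (
    StageSpec,
    build_2d_baseline,
    build_classifier,
    build_embedder,
    tiny_spec,
)
from .synth import (
    default_library,
    default_schedule,
    generate_embryo_series,
    make_temporal_only_pair,
    render_clip,
    thermal_timings,
)
from .taxonomy import EventLabel
from .train import (
    ArrayDataset,
    TrainConfig,
    evaluate,
    embed,
    first_frame_dataset,
    train_classifier,
    train_triplet,
)
from .video_io import Clip, ClipDataset, standardize_clip

#: CPU-scale optimisation settings used by every experiment below.  The
#: tiny specs need a far larger learning rate than the full-scale
#: protocol's 1e-6 to converge in a handful of epochs.
_LR = 1e-3

#: Effective sampled frame rate of the full-scale protocol (30 frames/s at
#: stride 10); synthetic clips are rendered directly at this rate.
_EFFECTIVE_FPS = 3.0


def _render_pair_dataset(
    motifs, n_per_class: int, seed: int, n_frames: int = 8, size: int = 32
) -> ArrayDataset:
    xs, ys = [], []
    for i in range(n_per_class):
        for label, motif in enumerate(motifs):
            clip = render_clip(motif, n_frames, size, seed=seed + i, frame_rate=_EFFECTIVE_FPS)
            xs.append(standardize_clip(clip, size))
            ys.append(label)
    return ArrayDataset(np.stack(xs), np.array(ys))


def temporal_information_experiment(
    seed: int = 0,
    n_train_per_class: int = 100,
    n_test_per_class: int = 50,
    n_seeds: int = 3,
    epochs: int = 12,
) -> dict:
    """3D classifier vs first-frame 2D baseline on a temporal-only task.

    Two classes share identical first frames (same static blob, same noise
    stream) and differ only in motion, so a first-frame classifier is at
    chance by construction while the video classifier can use the pulse.
    Returns mean top-1 for both models, their gap, and a binomial test of
    the 2D baseline against chance over the pooled test predictions.
    """
    pair = make_temporal_only_pair(seed)
    acc3d, acc2d = [], []
    correct_2d = total_2d = 0
    for rep in range(n_seeds):
        s = seed + rep
        train = _render_pair_dataset(pair, n_train_per_class, 10_000 * (rep + 1) + seed)
        test = _render_pair_dataset(pair, n_test_per_class, 900_000 + 10_000 * rep + seed)
        cfg = TrainConfig(learning_rate=_LR, epochs=epochs, batch_size=16, seed=s)

        spec = tiny_spec(input_shape=(8, 32, 32, 1), n_classes=2)
        net3d, _ = train_classifier(build_classifier(spec, seed=s), train, None, cfg)
        acc3d.append(evaluate(net3d, test, 2).top1_accuracy)

        net2d = build_2d_baseline(2, seed=s, stem_filters=8, widths=(8, 16), blocks=(1, 1))
        tr2, te2 = first_frame_dataset(train), first_frame_dataset(test)
        net2d, _ = train_classifier(net2d, tr2, te2, cfg)
        rep2d = evaluate(net2d, te2, 2)
        acc2d.append(rep2d.top1_accuracy)
        correct_2d += int(np.trace(rep2d.confusion_matrix))
        total_2d += int(rep2d.confusion_matrix.sum())

    p_chance = binomtest(correct_2d, total_2d, 0.5).pvalue
    return {
        "mean_top1_3d": float(np.mean(acc3d)),
        "mean_top1_2d": float(np.mean(acc2d)),
        "accuracy_gap": float(np.mean(acc3d) - np.mean(acc2d)),
        "p_2d_vs_chance": float(p_chance),
        "per_seed_3d": acc3d,
        "per_seed_2d": acc2d,
    }


def _render_embryo_cohort(n: int, seed: int, id_prefix: str, size: int = 32):
    """Hourly series for ``n`` embryos at the effective sampled frame rate."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sched = default_schedule(
            f"{id_prefix}{i:02d}", rng, frame_rate=_EFFECTIVE_FPS, clip_seconds=8 / _EFFECTIVE_FPS
        )
        tl, _ = generate_embryo_series(sched, seed=seed + 7919 * i, size=size)
        out.append((sched, tl))
    return out


def timing_recovery_experiment(
    seed: int = 0,
    n_train_embryos: int = 12,
    n_eval_embryos: int = 20,
    epochs: int = 30,
    balance: bool = False,
) -> dict:
    """End-to-end onset recovery on embryos with known schedules.

    Trains the tiny classifier on hourly clips of a training cohort
    (labelled by the previous-event rule), predicts probability
    trajectories for a held-out cohort, extracts onsets with the
    peak/threshold rules, and scores the fraction of (embryo, event) pairs
    recovered within +/- 1 hour of the scheduled ground truth.
    """
    train_cohort = _render_embryo_cohort(n_train_embryos, seed + 1000, "train")
    eval_cohort = _render_embryo_cohort(n_eval_embryos, seed + 500_000, "eval")

    clips, labels, ids = [], [], []
    for sched, tl in train_cohort:
        for h, c in zip(tl.hours, tl.clips):
            clips.append(c.frames)
            labels.append(sched.label_at(h))
            ids.append(f"{sched.embryo_id}_h{h}")
    ds = ClipDataset(clips, labels, ids)
    if balance:
        ds = balance_classes(ds, seed=seed)
    xs = np.stack([standardize_clip(Clip(c), 32) for c in ds.clips])
    data = ArrayDataset(xs, np.array([int(l) for l in ds.labels]))

    spec = tiny_spec(input_shape=(8, 32, 32, 1), n_classes=10)
    cfg = TrainConfig(learning_rate=_LR, epochs=epochs, batch_size=32, seed=seed)
    net, history = train_classifier(build_classifier(spec, seed=seed), data, None, cfg)

    n_ok = n_total = 0
    abs_errors = []
    for sched, tl in eval_cohort:
        traj = predict_trajectory(net, tl, size=32, stride=1, n_source_frames=8)
        timing = extract_timing(traj)
        for ev, true_h in sched.onsets.items():
            n_total += 1
            got = timing.onsets.get(ev)
            if got is not None:
                abs_errors.append(abs(got - true_h))
                if abs(got - true_h) <= 1:
                    n_ok += 1
    return {
        "recovery_within_1h": n_ok / n_total,
        "n_pairs": n_total,
        "mean_abs_error_h": float(np.mean(abs_errors)) if abs_errors else float("nan"),
        "final_train_accuracy": float(history["accuracy"].iloc[-1]),
        "model": net,
        "eval_cohort": eval_cohort,
    }


def triplet_separation_experiment(
    seed: int = 0,
    n_train_per_class: int = 40,
    n_test_per_class: int = 20,
    epochs: int = 15,
) -> dict:
    """Metric-learning separation of three well-separated synthetic classes.

    Trains the embedding head with semi-hard triplet loss and reports
    held-out mean intra- vs inter-class embedding distances, the maximum
    deviation from unit norm, and the per-class silhouette in the 2D
    linear (PCA) projection.
    """
    lib = default_library()
    motifs = [lib[EventLabel.GASTRULA], lib[EventLabel.EYE_SPOTS], lib[EventLabel.HATCH]]
    train = _render_pair_dataset(motifs, n_train_per_class, 30_000 + seed)
    test = _render_pair_dataset(motifs, n_test_per_class, 960_000 + seed)

    spec = tiny_spec(input_shape=(8, 32, 32, 1), n_classes=3, head="l2_embedding")
    cfg = TrainConfig(
        loss="triplet_semi_hard", learning_rate=_LR, epochs=epochs, batch_size=24, seed=seed
    )
    net, _ = train_triplet(build_embedder(spec, seed=seed), train, cfg)

    emb = embed(net, test.x)
    norm_dev = float(np.abs(np.linalg.norm(emb, axis=1) - 1.0).max())
    d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
    same = test.y[:, None] == test.y[None, :]
    off = ~np.eye(len(emb), dtype=bool)
    intra = float(d[same & off].mean())
    inter = float(d[~same].mean())
    proj = project_embeddings(emb, "linear_pca", labels=test.y, seed=seed)
    sil = float(silhouette_score(proj[["x", "y"]].to_numpy(), test.y))
    return {
        "mean_intra_distance": intra,
        "mean_inter_distance": inter,
        "max_unit_norm_deviation": norm_dev,
        "silhouette_2d": sil,
        "embeddings": emb,
        "labels": test.y,
    }


def stride_sweep_experiment(
    seed: int = 0,
    strides: tuple[int, ...] = (3, 5, 10),
    n_per_class: int = 50,
    n_seeds: int = 3,
    epochs: int = 8,
    source_fps: float = 7.5,
    source_seconds: float = 4.0,
) -> dict:
    """Temporal-stride sweep on spatially separable (static) classes.

    With static motifs, temporal subsampling discards no information, so
    the stride grid should produce statistically indistinguishable
    accuracies (overlapping mean +/- 2 s.e. bands across seeds) — the null
    result expected when temporal detail is irrelevant to the classes.
    """
    lib = default_library()
    statics = [
        lib[EventLabel.PRE_GASTRULA],
        lib[EventLabel.GASTRULA],
        lib[EventLabel.EYE_SPOTS],
        lib[EventLabel.HATCH],
    ]
    n_source = int(round(source_fps * source_seconds))
    results: dict[int, list[float]] = {s: [] for s in strides}
    for rep in range(n_seeds):
        s = seed + rep
        rng_seed = 40_000 + 10_000 * rep + seed
        full_train = _render_pair_dataset(statics, n_per_class, rng_seed, n_frames=n_source)
        full_test = _render_pair_dataset(statics, n_per_class // 2, rng_seed + 5_000, n_frames=n_source)
        for stride in strides:
            tr = ArrayDataset(full_train.x[:, ::stride], full_train.y)
            te = ArrayDataset(full_test.x[:, ::stride], full_test.y)
            spec = tiny_spec(input_shape=tuple(tr.x.shape[1:]), n_classes=len(statics))
            cfg = TrainConfig(learning_rate=_LR, epochs=epochs, batch_size=16, seed=s)
            net, _ = train_classifier(build_classifier(spec, seed=s), tr, None, cfg)
            results[stride].append(evaluate(net, te, len(statics)).top1_accuracy)
    bands = {}
    for stride, accs in results.items():
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
        bands[stride] = (float(accs.mean() - 2 * se), float(accs.mean() + 2 * se))
    overlap = all(
        bands[a][0] <= bands[b][1] and bands[b][0] <= bands[a][1]
        for a in strides for b in strides
    )
    return {
        "per_stride_accuracy": {s: list(map(float, v)) for s, v in results.items()},
        "bands_2se": bands,
        "all_bands_overlap": overlap,
    }


def thermal_recovery_experiment(seed: int = 0, n_per_treatment: int = 20) -> dict:
    """T_opt recovery from synthetic thermally plastic timings.

    The generator builds in a lower optimum temperature for late events;
    the summary pipeline must recover T_opt(late) < T_opt(early) from the
    per-embryo timings alone.
    """
    timings = thermal_timings(n_per_treatment=n_per_treatment, seed=seed)
    summary = summarize_treatments(timings)
    early = thermal_curve(summary, EventLabel.GASTRULA)
    late = thermal_curve(summary, EventLabel.HATCH)
    return {
        "t_opt_early": early.t_opt,
        "t_opt_late": late.t_opt,
        "t_opt_shift_detected": late.t_opt < early.t_opt,
        "summary": summary,
    }
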