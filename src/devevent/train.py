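"""Training and evaluation for the classifier, the embedder and ablations.

The classifier protocol is sparse categorical cross-entropy with Adam at a
fixed learning rate of 1e-6 for 50 epochs and batch size 32; the triplet
embedder uses semi-hard triplet loss with Adam at 1e-3 for 20 epochs.
Those are the defaults of :class:`TrainConfig`; CPU-scale experiments pass
smaller epoch counts and a larger learning rate explicitly.

Final-epoch weights are used (no early stopping or best-validation
checkpointing); the validation set is monitored each epoch but never used
for selection.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelSpec, build_2d_baseline, build_classifier, tiny_spec
from .nn import Adam, softmax, softmax_cross_entropy, triplet_semihard_loss
from .nn.networks import Sequential
from .taxonomy import N_CLASSES
from .video_io import Clip, ClipDataset, split_dataset, standardize_clip, subsample_clip


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol; defaults follow the classifier protocol."""

    loss: str = "sparse_categorical_cross_entropy"
    learning_rate: float = 1e-6
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    n_repeats: int = 3
    triplet_margin: float = 1.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("sparse_categorical_cross_entropy", "triplet_semi_hard"):
            raise ValueError(f"unknown loss: {self.loss!r}")

    @classmethod
    def triplet_default(cls, **kw) -> "TrainConfig":
        return cls(loss="triplet_semi_hard", learning_rate=1e-3, epochs=20, **kw)


@dataclass
class ArrayDataset:
    """Model-ready samples: float32 inputs in [0, 1] plus integer labels."""

    x: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have equal first dimension")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(len(self.y))]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(self.x[idx], self.y[idx], [self.sample_ids[i] for i in idx])


def to_arrays(dataset: ClipDataset, size: int | None = None) -> ArrayDataset:
    """Standardise a clip dataset into a stacked model-input array."""
    xs = []
    for clip in dataset.clips:
        c = clip if isinstance(clip, Clip) else Clip(clip)
        s = size if size is not None else c.frames.shape[1]
        xs.append(standardize_clip(c, size=s))
    x = np.stack(xs)
    y = np.array([int(lab) for lab in dataset.labels], dtype=np.int64)
    return ArrayDataset(x, y, list(dataset.sample_ids))


def first_frame_dataset(data: ArrayDataset) -> ArrayDataset:
    """Reduce each video sample to only its first frame (for the 2D baseline)."""
    return ArrayDataset(data.x[:, 0], data.y, list(data.sample_ids))


def predict_proba(model: Sequential, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Eval-mode class probabilities, batched."""
    outs = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], training=False)
        outs.append(softmax(logits))
    return np.concatenate(outs, axis=0)


def _check_labels(y: np.ndarray, n_classes: int) -> None:
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValueError(
            f"labels must lie in 0..{n_classes - 1}; found range [{y.min()}, {y.max()}]"
        )


def train_classifier(
    model: Sequential,
    train_set: ArrayDataset,
    val_set: ArrayDataset | None,
    config: TrainConfig,
) -> tuple[Sequential, pd.DataFrame]:
    """Fit the classifier; returns the model and a per-epoch history table.

    Fully seeded: the data order is drawn from ``config.seed`` and the
    weight initialisation from the builder's seed, so identical
    (model seed, config) reruns give identical final weights.
    """
    n_classes = model.forward(train_set.x[:1]).shape[1]
    _check_labels(train_set.y, n_classes)
    if val_set is not None:
        _check_labels(val_set.y, n_classes)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), learning_rate=config.learning_rate)
    history = []
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = train_set.x[idx], train_set.y[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch,
            "loss": float(np.sum(losses) / n),
            "accuracy": correct / n,
        }
        if val_set is not None and len(val_set):
            vp = predict_proba(model, val_set.x, config.batch_size)
            eps = 1e-12
            row["val_loss"] = float(
                -np.log(vp[np.arange(len(val_set)), val_set.y] + eps).mean()
            )
            row["val_accuracy"] = float((vp.argmax(axis=1) == val_set.y).mean())
        history.append(row)
    return model, pd.DataFrame(history)


@dataclass
class EvalReport:
    """Test-set evaluation: top-1 accuracy, confusion matrix, recalls.

    Confusion-matrix rows are ground truth, columns predictions; row sums
    equal the per-class test counts regardless of prediction quality.
    """

    top1_accuracy: float
    confusion_matrix: np.ndarray
    per_class_recall: np.ndarray
    seed: int = 0
    runtime_s: float = 0.0

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES,
        seed: int = 0, runtime_s: float = 0.0,
    ) -> "EvalReport":
        cm = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(cm, (y_true, y_pred), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            recall = np.where(cm.sum(1) > 0, np.diag(cm) / np.maximum(cm.sum(1), 1), np.nan)
        top1 = float(np.trace(cm) / max(cm.sum(), 1))
        return cls(top1, cm, recall, seed, runtime_s)


def evaluate(model: Sequential, test_set: ArrayDataset, n_classes: int | None = None,
             batch_size: int = 32, seed: int = 0) -> EvalReport:
    """Evaluate a trained model on a held-out set."""
    if len(test_set) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    t0 = time.time()
    probs = predict_proba(model, test_set.x, batch_size)
    if n_classes is None:
        n_classes = probs.shape[1]
    _check_labels(test_set.y, n_classes)
    return EvalReport.from_predictions(
        test_set.y, probs.argmax(axis=1), n_classes, seed, time.time() - t0
    )


def mean_top1(reports: list[EvalReport]) -> float:
    return float(np.mean([r.top1_accuracy for r in reports]))


def _triplet_batches(
    y: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-balanced batches guaranteeing >= 2 classes with >= 2 samples."""
    classes = [c for c in np.unique(y) if (y == c).sum() >= 2]
    if len(classes) < 2:
        raise ValueError("triplet training needs >= 2 classes with >= 2 samples each")
    per_class = {c: np.flatnonzero(y == c) for c in classes}
    n_batches = max(1, len(y) // batch_size)
    k = max(2, batch_size // len(classes))
    batches = []
    for _ in range(n_batches):
        chosen = classes if len(classes) * k <= batch_size else list(
            rng.choice(classes, size=max(2, batch_size // k), replace=False)
        )
        idx = np.concatenate(
            [rng.choice(per_class[c], size=min(k, len(per_class[c])), replace=False)
             for c in chosen]
        )
        batches.append(idx)
    return batches


def train_triplet(
    embedder: Sequential, train_set: ArrayDataset, config: TrainConfig
) -> tuple[Sequential, pd.DataFrame]:
    """Fit the embedder with semi-hard triplet loss.

    Batches are class-balanced so every batch contains valid triplets; a
    batch that still yields none is skipped and counted in a warning.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(embedder.params(), learning_rate=config.learning_rate)
    history = []
    skipped = 0
    for epoch in range(config.epochs):
        losses = []
        for idx in _triplet_batches(train_set.y, config.batch_size, rng):
            emb = embedder.forward(train_set.x[idx], training=True)
            loss, demb, n_pairs = triplet_semihard_loss(
                emb, train_set.y[idx], config.triplet_margin
            )
            if n_pairs == 0:
                skipped += 1
                continue
            opt.zero_grad()
            embedder.backward(demb.astype(np.float32))
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan})
    if skipped:
        warnings.warn(f"{skipped} batches skipped: no valid triplet", stacklevel=2)
    return embedder, pd.DataFrame(history)


def embed(embedder: Sequential, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(embedder.forward(x[i : i + batch_size], training=False))
    return np.concatenate(outs, axis=0)


ABLATION_VARIANTS = (
    "baseline_2d",
    "stride=3", "stride=5", "stride=10",
    "length=4", "length=8", "length=16",
)


def run_ablation(
    variant: str,
    dataset: ClipDataset,
    config: TrainConfig,
    spec: ModelSpec | None = None,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    frame_rate: float = 30.0,
    base_stride: int = 10,
    base_seconds: float = 4.0,
    baseline_widths: tuple[int, ...] = (8, 16),
    baseline_blocks: tuple[int, ...] = (1, 1),
    baseline_stem: int = 8,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Train/evaluate one ablation variant across ``config.n_repeats`` seeds.

    ``dataset`` holds source-resolution clips (full frame rate).  Variants:

    * ``baseline_2d`` — 2D residual classifier on only the first frame of
      each subsampled video sample.
    * ``stride=k`` — temporal stride k over the same ``base_seconds`` of
      footage (paper grid: 3, 5, 10).
    * ``length=s`` — s seconds of footage at the same ``base_stride``
      (paper grid: 4, 8, 16).

    Each repeat re-draws both the split and the weight initialisation.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {ABLATION_VARIANTS}")
    stride, seconds = base_stride, base_seconds
    if variant.startswith("stride="):
        stride = int(variant.split("=")[1])
    elif variant.startswith("length="):
        seconds = float(variant.split("=")[1])
    n_source = int(round(seconds * frame_rate))

    sub = ClipDataset(
        [subsample_clip(Clip(c), 0, n_source, stride).frames for c in dataset.clips],
        list(dataset.labels),
        list(dataset.sample_ids),
    )
    data = to_arrays(sub)
    n_classes = int(data.y.max()) + 1
    size = data.x.shape[2]
    reports = []
    for rep in range(config.n_repeats):
        seed = config.seed + rep
        idx_train, idx_val, idx_test = split_dataset(list(range(len(data))), fractions, seed)
        tr, va, te = data.subset(idx_train), data.subset(idx_val), data.subset(idx_test)
        cfg = replace(config, seed=seed)
        if variant == "baseline_2d":
            model = build_2d_baseline(
                n_classes, seed=seed, stem_filters=baseline_stem,
                widths=baseline_widths, blocks=baseline_blocks,
            )
            tr, va, te = (first_frame_dataset(d) for d in (tr, va, te))
        else:
            model_spec = spec or tiny_spec(
                input_shape=(data.x.shape[1], size, size, 1), n_classes=n_classes
            )
            if spec is not None:
                model_spec = replace(
                    spec, input_shape=(data.x.shape[1], size, size, 1), n_classes=n_classes
                )
            model = build_classifier(model_spec, seed=seed)
        model, _ = train_classifier(model, tr, va, cfg)
        reports.append(evaluate(model, te, n_classes, cfg.batch_size, seed))
    table = pd.DataFrame(
        {"variant": variant, "seed": r.seed, "top1_accuracy": r.top1_accuracy}
        for r in reports
    )
    return reports, table


def compare_variants(results: dict[str, list[EvalReport]]) -> pd.DataFrame:
    """Paired comparison of mean top-1 accuracy with mean +/- 2 s.e. bands."""
    rows = []
    for variant, reports in results.items():
        accs = np.array([r.top1_accuracy for r in reports])
        se = accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0
        rows.append(
            {
                "variant": variant,
                "n_seeds": len(accs),
                "mean_top1": accs.mean(),
                "sd": accs.std(ddof=1) if len(accs) > 1 else 0.0,
                "se": se,
                "lo_2se": accs.mean() - 2 * se,
                "hi_2se": accs.mean() + 2 * se,
            }
        )
    return pd.DataFrame(rows)
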