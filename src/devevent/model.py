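"""Dev-ResNet architecture: a small (2+1)D residual video classifier.

The network factorises every 3D convolution into a 2D spatial convolution
(kernel 1x3x3) followed by a 1D temporal convolution (kernel 3x1x1), each
with batch normalisation and ReLU.  A light stem (conv + BN + ReLU + 3D
max-pool) downsamples the input video, four residual stages build
spatio-temporal features, and a 3D global average pool plus a fully
connected layer performs 10-way classification.  The default configuration
totals ~5.2 million trainable parameters and ~3.7 GFLOPs for a forward
pass on a 12x128x128x1 clip (2 operations per multiply-accumulate).

Three builders are provided:

* :func:`build_classifier` — the softmax classifier.
* :func:`build_embedder` — the metric-learning variant: the classification
  layer is replaced by a linear fully connected layer of the same width as
  the preceding average pool, followed by L2 normalisation.
* :func:`build_2d_baseline` — a ResNet-18-style 2D classifier consuming a
  single frame, used to quantify the value of temporal information.

Parameter and FLOP counting is analytic, driven by the same layer plan the
builders consume, and verified against the built networks in the tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .nn.layers import (
    BatchNorm,
    Conv2D,
    Dense,
    GlobalAvgPool,
    L2Normalize,
    Layer,
    MaxPool2D,
    MaxPool3D,
    ReLU,
    SpatialConv3D,
)
from .nn.networks import ResBlock2D, ResBlock21D, Sequential, mid_channels

_OPS_PER_MAC = 2  # documented convention; 1 counts a MAC as a single op


@dataclass(frozen=True)
class StageSpec:
    """One residual stage: ``n_blocks`` blocks of ``filters`` channels.

    ``stride`` (1 or 2) applies to the first block and halves frames,
    height and width when 2.
    """

    n_blocks: int
    filters: int
    stride: int

    def validate(self, name: str) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"{name}: n_blocks must be >= 1")
        if self.filters <= 0:
            raise ValueError(f"{name}: filters must be > 0")
        if self.stride not in (1, 2):
            raise ValueError(f"{name}: stride must be 1 or 2")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the (2+1)D classifier."""

    input_shape: tuple[int, int, int, int] = (12, 128, 128, 1)
    n_classes: int = 10
    stem_filters: int = 16
    stem_kernel: int = 3  # spatial kernel; temporal extent is 1
    stem_stride: tuple[int, int, int] = (1, 2, 2)
    stem_pool: tuple[int, int, int] = (1, 2, 2)
    stages: tuple[StageSpec, ...] = (
        StageSpec(2, 40, 1),
        StageSpec(2, 96, 2),
        StageSpec(2, 192, 2),
        StageSpec(2, 256, 2),
    )
    spatial_kernel: int = 3
    temporal_kernel: int = 3
    mid_channel_policy: str = "equal_to_out"
    head: str = "softmax_classifier"

    def validate(self) -> None:
        if self.head not in ("softmax_classifier", "l2_embedding"):
            raise ValueError(f"unknown head: {self.head!r}")
        if self.mid_channel_policy not in ("equal_to_out", "matched_3d"):
            raise ValueError(f"unknown mid_channel_policy: {self.mid_channel_policy!r}")
        if len(self.input_shape) != 4:
            raise ValueError("input_shape must be (L, H, W, C)")
        for i, st in enumerate(self.stages):
            st.validate(f"stage {i}")

    def with_head(self, head: str) -> "ModelSpec":
        return dataclasses.replace(self, head=head)

    @property
    def embedding_dim(self) -> int:
        """Width of the pooled features (== embedding width for the embedder)."""
        return self.stages[-1].filters

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = [list(dataclasses.astuple(s)) for s in self.stages]
        d["input_shape"] = list(self.input_shape)
        d["stem_stride"] = list(self.stem_stride)
        d["stem_pool"] = list(self.stem_pool)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(StageSpec(*s) for s in d["stages"])
        for key in ("input_shape", "stem_stride", "stem_pool"):
            if key in d:
                d[key] = tuple(d[key])
        spec = cls(**d)
        spec.validate()
        return spec


DEFAULT_SPEC = ModelSpec()


def tiny_spec(
    input_shape: tuple[int, int, int, int] = (8, 32, 32, 1),
    n_classes: int = 10,
    stem_filters: int = 8,
    stages: tuple[StageSpec, ...] = (StageSpec(1, 8, 1), StageSpec(1, 16, 2)),
    head: str = "softmax_classifier",
) -> ModelSpec:
    """A small spec for CPU-scale experiments on low-resolution clips."""
    return ModelSpec(
        input_shape=input_shape,
        n_classes=n_classes,
        stem_filters=stem_filters,
        stages=stages,
        head=head,
    )


@dataclass
class LayerInfo:
    """One row of the shape trace: layer name, output shape, cost."""

    name: str
    out_shape: tuple[int, ...]
    n_params: int
    macs: int


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def _plan(spec: ModelSpec) -> Iterator[LayerInfo]:
    """Walk the architecture, yielding shapes, parameter and MAC counts.

    This is the single source of truth for the layer layout; the builder
    consumes the same stage description, and the tests assert the built
    network's parameter total equals the analytic one.
    """
    spec.validate()
    l, h, w, c = spec.input_shape
    sk, tk = spec.spatial_kernel, spec.temporal_kernel

    st_l, st_h, st_w = spec.stem_stride
    l, h, w = _ceil_div(l, st_l), _ceil_div(h, st_h), _ceil_div(w, st_w)
    f = spec.stem_filters
    yield LayerInfo(
        f"stem/conv1x{spec.stem_kernel}x{spec.stem_kernel}",
        (l, h, w, f),
        spec.stem_kernel**2 * c * f + f,
        spec.stem_kernel**2 * c * f * l * h * w,
    )
    yield LayerInfo("stem/bn", (l, h, w, f), 2 * f, 0)
    pl, ph, pw = spec.stem_pool
    l, h, w = _ceil_div(l, pl), _ceil_div(h, ph), _ceil_div(w, pw)
    yield LayerInfo("stem/maxpool", (l, h, w, f), 0, 0)
    cin = f

    for si, stage in enumerate(spec.stages):
        for bi in range(stage.n_blocks):
            s = stage.stride if bi == 0 else 1
            if s == 2:
                l, h, w = _ceil_div(l, 2), _ceil_div(h, 2), _ceil_div(w, 2)
            f = stage.filters
            vox = l * h * w
            name = f"stage{si + 1}/block{bi + 1}"
            m1 = mid_channels(spec.mid_channel_policy, tk, sk, cin, f)
            m2 = mid_channels(spec.mid_channel_policy, tk, sk, f, f)
            for tag, k2, ci, co in (
                ("conv_s1", sk**2, cin, m1),
                ("conv_t1", tk, m1, f),
                ("conv_s2", sk**2, f, m2),
                ("conv_t2", tk, m2, f),
            ):
                yield LayerInfo(f"{name}/{tag}", (l, h, w, co), k2 * ci * co + co, k2 * ci * co * vox)
                yield LayerInfo(f"{name}/bn_{tag}", (l, h, w, co), 2 * co, 0)
            if s == 2 or cin != f:
                yield LayerInfo(f"{name}/proj", (l, h, w, f), cin * f + f, cin * f * vox)
                yield LayerInfo(f"{name}/bn_proj", (l, h, w, f), 2 * f, 0)
            cin = f

    yield LayerInfo("global_avg_pool", (cin,), 0, 0)
    if spec.head == "softmax_classifier":
        out = spec.n_classes
        yield LayerInfo("fc", (out,), cin * out + out, cin * out)
    else:
        out = cin
        yield LayerInfo("fc_embed", (out,), cin * out + out, cin * out)
        yield LayerInfo("l2_normalize", (out,), 0, 0)


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count (convolution/dense weights and
    biases plus batch-norm scale/offset), computed layer by layer."""
    return sum(info.n_params for info in _plan(spec))


def count_flops(
    spec: ModelSpec,
    input_shape: tuple[int, int, int, int] | None = None,
    ops_per_mac: int = _OPS_PER_MAC,
) -> float:
    """Forward-pass floating-point operations for one clip.

    Counts convolution and dense multiply-accumulates (``ops_per_mac``
    operations each; default 2).  Batch-norm and activations are excluded
    as negligible.
    """
    if input_shape is not None:
        spec = dataclasses.replace(spec, input_shape=tuple(input_shape))
    return float(sum(info.macs for info in _plan(spec)) * ops_per_mac)


def shape_table(spec: ModelSpec) -> pd.DataFrame:
    """Machine-readable layer table: name, output shape, params, MACs."""
    rows = [
        {
            "layer": info.name,
            "out_shape": "x".join(map(str, info.out_shape)),
            "params": info.n_params,
            "macs": info.macs,
        }
        for info in _plan(spec)
    ]
    return pd.DataFrame(rows)


def summarize(spec: ModelSpec) -> str:
    """Human-readable model summary with totals."""
    table = shape_table(spec)
    total_p = int(table["params"].sum())
    gflops = count_flops(spec) / 1e9
    lines = [table.to_string(index=False)]
    lines.append(f"total parameters: {total_p:,} (~{total_p / 1e6:.1f}M)")
    lines.append(f"forward pass: {gflops:.2f} GFLOPs at input {spec.input_shape} "
                 f"({_OPS_PER_MAC} ops per MAC)")
    return "\n".join(lines)


def build_classifier(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Build the (2+1)D softmax classifier.

    The returned network maps ``(batch, L, H, W, C)`` to logits
    ``(batch, n_classes)``; apply :func:`devevent.nn.softmax` (or use the
    training utilities) for probabilities.
    """
    if spec.head != "softmax_classifier":
        raise ValueError("build_classifier requires head='softmax_classifier'")
    return _build(spec, seed)


def build_embedder(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Build the embedding variant: linear FC (same width as the pooled
    features) followed by L2 normalisation, so outputs lie on the unit
    sphere."""
    if spec.head != "l2_embedding":
        spec = spec.with_head("l2_embedding")
    return _build(spec, seed)


def _build(spec: ModelSpec, seed: int) -> Sequential:
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        _StemConv(rng, spec),
        BatchNorm(spec.stem_filters),
        ReLU(),
        MaxPool3D(spec.stem_pool),
    ]
    cin = spec.stem_filters
    for stage in spec.stages:
        for bi in range(stage.n_blocks):
            s = stage.stride if bi == 0 else 1
            layers.append(
                ResBlock21D(
                    rng,
                    cin,
                    stage.filters,
                    s,
                    spec.spatial_kernel,
                    spec.temporal_kernel,
                    spec.mid_channel_policy,
                )
            )
            cin = stage.filters
    layers.append(GlobalAvgPool())
    if spec.head == "softmax_classifier":
        layers.append(Dense(rng, cin, spec.n_classes))
    else:
        layers.append(Dense(rng, cin, cin))
        layers.append(L2Normalize())
    net = Sequential(layers)
    net.spec = spec
    return net


class _StemConv(SpatialConv3D):
    """Stem convolution: spatial kernel with temporal extent 1."""

    def __init__(self, rng, spec: ModelSpec):
        st_l, st_h, st_w = spec.stem_stride
        if st_h != st_w:
            raise ValueError("stem_stride must be square in H and W")
        super().__init__(
            rng,
            spec.stem_kernel,
            spec.input_shape[-1],
            spec.stem_filters,
            stride=st_h,
            t_stride=st_l,
        )


def save_model(net: Sequential, path) -> None:
    """Serialise a spec-built network (weights + spec) to an .npz file."""
    import json

    if getattr(net, "spec", None) is None:
        raise ValueError("save_model supports spec-built networks only")
    arrays = {f"w{i}": p.value for i, p in enumerate(net.params())}
    np.savez(path, meta=json.dumps(net.spec.to_dict()), **arrays)


def load_model(path) -> Sequential:
    """Rebuild a network saved by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec.from_dict(json.loads(str(data["meta"])))
        builder = build_classifier if spec.head == "softmax_classifier" else build_embedder
        net = builder(spec, seed=0)
        net.set_weights([data[f"w{i}"] for i in range(len(net.params()))])
    return net


def build_2d_baseline(
    n_classes: int = 10,
    seed: int = 0,
    in_channels: int = 1,
    stem_filters: int = 64,
    widths: tuple[int, ...] = (64, 128, 256, 512),
    blocks: tuple[int, ...] = (2, 2, 2, 2),
) -> Sequential:
    """ResNet-18-style 2D classifier on single frames (N, H, W, C).

    Defaults give the standard 18-layer layout (~11.2M parameters with 10
    classes); pass smaller ``widths``/``blocks`` for CPU-scale runs.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv2D(rng, 7, in_channels, stem_filters, stride=2),
        BatchNorm(stem_filters),
        ReLU(),
        MaxPool2D((2, 2)),
    ]
    cin = stem_filters
    for si, (nb, f) in enumerate(zip(blocks, widths, strict=True)):
        for bi in range(nb):
            s = 2 if (si > 0 and bi == 0) else 1
            layers.append(ResBlock2D(rng, cin, f, s))
            cin = f
    layers.append(GlobalAvgPool())
    layers.append(Dense(rng, cin, n_classes))
    net = Sequential(layers)
    net.spec = None
    return net
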