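"""Architecture contracts: parameter counts, FLOPs, shapes, determinism."""

import dataclasses

import numpy as np
import pytest

from devevent.model import (
    DEFAULT_SPEC,
    ModelSpec,
    StageSpec,
    build_2d_baseline,
    build_classifier,
    build_embedder,
    count_flops,
    count_parameters,
    load_model,
    save_model,
    shape_table,
    tiny_spec,
)
from devevent.nn import softmax


def test_default_spec_parameter_count_is_5_2_million():
    analytic = count_parameters(DEFAULT_SPEC)
    built = build_classifier(DEFAULT_SPEC, seed=0).n_params()
    assert analytic == built
    assert round(analytic / 1e6, 1) == 5.2


def test_default_spec_flops_is_3_7_gflops_at_full_input():
    flops = count_flops(DEFAULT_SPEC, input_shape=(12, 128, 128, 1), ops_per_mac=2)
    assert round(flops / 1e9, 1) == 3.7


def test_single_conv_parameter_closed_form():
    # a lone 1x3x3 convolution from 1 channel to F filters with bias: 9F + F
    for f in (4, 16, 40):
        spec = ModelSpec(
            input_shape=(2, 16, 16, 1), n_classes=2, stem_filters=f,
            stages=(StageSpec(1, f, 1),),
        )
        table = shape_table(spec)
        stem = table[table.layer.str.startswith("stem/conv")].iloc[0]
        assert stem.params == 9 * f + f


def test_parameter_count_independent_of_input_extent():
    a = dataclasses.replace(DEFAULT_SPEC, input_shape=(12, 128, 128, 1))
    b = dataclasses.replace(DEFAULT_SPEC, input_shape=(24, 64, 64, 1))
    assert count_parameters(a) == count_parameters(b)


def test_flops_spatial_proportionality():
    base = count_flops(DEFAULT_SPEC, input_shape=(12, 128, 128, 1))
    half = count_flops(DEFAULT_SPEC, input_shape=(12, 64, 64, 1))
    assert half == pytest.approx(base / 4, rel=0.02)


@pytest.mark.parametrize("n_random", [20])
def test_analytic_count_matches_built_network_for_random_specs(n_random):
    rng = np.random.default_rng(7)
    for _ in range(n_random):
        n_stages = int(rng.integers(1, 4))
        stages = tuple(
            StageSpec(int(rng.integers(1, 3)), int(rng.choice([4, 8, 12, 16])),
                      int(rng.choice([1, 2])))
            for _ in range(n_stages)
        )
        spec = ModelSpec(
            input_shape=(4, 16, 16, 1),
            n_classes=int(rng.integers(2, 11)),
            stem_filters=int(rng.choice([4, 8])),
            stages=stages,
            mid_channel_policy=str(rng.choice(["equal_to_out", "matched_3d"])),
        )
        assert count_parameters(spec) == build_classifier(spec, seed=1).n_params()


def test_stride2_stage_halves_every_feature_axis():
    spec = tiny_spec(input_shape=(8, 32, 32, 1))
    table = shape_table(spec)
    # stem: (1,2,2) stride then (1,2,2) pool -> 8x8x8; stage2 s2 -> 4x4x4
    assert table[table.layer == "stem/maxpool"].iloc[0].out_shape == "8x8x8x8"
    s2 = table[table.layer.str.startswith("stage2/block1/conv_s1")].iloc[0]
    assert s2.out_shape.startswith("4x4x4")


def test_classifier_outputs_probabilities_and_batch_independence():
    spec = tiny_spec(input_shape=(4, 16, 16, 1), n_classes=10)
    net = build_classifier(spec, seed=0)
    x = np.random.default_rng(0).random((4, 4, 16, 16, 1)).astype(np.float32)
    p1 = softmax(net.forward(x[:2]))
    p2 = softmax(net.forward(np.concatenate([x, x])))
    assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
    assert np.isfinite(p1).all()
    # eval-mode outputs do not depend on batch composition
    np.testing.assert_allclose(p2[:2], p1, atol=1e-6)
    # and repeated forward passes are bit-identical
    np.testing.assert_array_equal(net.forward(x), net.forward(x))


def test_embedder_width_equals_final_stage_filters():
    spec = tiny_spec(input_shape=(4, 16, 16, 1), head="l2_embedding")
    net = build_embedder(spec, seed=0)
    x = np.random.default_rng(1).random((3, 4, 16, 16, 1)).astype(np.float32)
    emb = net.forward(x)
    assert emb.shape == (3, spec.embedding_dim)
    assert spec.embedding_dim == spec.stages[-1].filters
    np.testing.assert_allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-5)
    # identical inputs -> identical embeddings
    np.testing.assert_array_equal(net.forward(x[:1]), net.forward(x[:1]))


def test_2d_baseline_is_resnet18_scale():
    net = build_2d_baseline(n_classes=10)
    assert net.n_params() == pytest.approx(11.2e6, rel=0.01)
    x = np.zeros((2, 128, 128, 1), np.float32)
    p = softmax(net.forward(x))
    assert p.shape == (2, 10)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_invalid_specs_are_rejected():
    with pytest.raises(ValueError, match="stage 0"):
        ModelSpec(stages=(StageSpec(2, 0, 1),)).validate()
    with pytest.raises(ValueError, match="stride"):
        ModelSpec(stages=(StageSpec(2, 8, 3),)).validate()
    with pytest.raises(ValueError, match="head"):
        ModelSpec(head="regression").validate()


def test_model_save_load_roundtrip(tmp_path):
    spec = tiny_spec(input_shape=(4, 16, 16, 1), n_classes=4)
    net = build_classifier(spec, seed=5)
    x = np.random.default_rng(2).random((2, 4, 16, 16, 1)).astype(np.float32)
    before = net.forward(x)
    save_model(net, tmp_path / "w.npz")
    loaded = load_model(tmp_path / "w.npz")
    np.testing.assert_array_equal(loaded.forward(x), before)
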