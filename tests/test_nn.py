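"""Numerical correctness of the layer library: gradients, shapes, norms."""

import numpy as np
import pytest

from devevent.model import build_classifier, build_embedder, tiny_spec
from devevent.nn import (
    softmax_cross_entropy,
    triplet_semihard_loss,
)
from devevent.nn.layers import BatchNorm, MaxPool3D, _same_pad


def _directional_check(net, x, loss_of_logits, tol=0.03, eps=1e-3):
    """Compare the analytic directional derivative over all parameters
    against a central finite difference along a random direction."""
    params = net.params()
    for p in params:
        p.zero_grad()
    out = net.forward(x, training=False)
    _, dout = loss_of_logits(out)
    net.backward(dout.astype(np.float32))
    rng = np.random.default_rng(123)
    dirs = [rng.normal(size=p.value.shape).astype(np.float32) for p in params]
    analytic = sum(float((p.grad * d).sum()) for p, d in zip(params, dirs))
    for p, d in zip(params, dirs):
        p.value += eps * d
    lp, _ = loss_of_logits(net.forward(x, training=False))
    for p, d in zip(params, dirs):
        p.value -= 2 * eps * d
    lm, _ = loss_of_logits(net.forward(x, training=False))
    for p, d in zip(params, dirs):
        p.value += eps * d
    numeric = (lp - lm) / (2 * eps)
    assert analytic == pytest.approx(numeric, rel=tol, abs=1e-4)


def test_classifier_backprop_matches_finite_differences():
    rng = np.random.default_rng(0)
    net = build_classifier(tiny_spec(input_shape=(4, 16, 16, 1), n_classes=5), seed=2)
    x = rng.random((6, 4, 16, 16, 1)).astype(np.float32)
    y = np.array([0, 1, 2, 3, 4, 0])

    def ce(logits):
        loss, dlogits, _ = softmax_cross_entropy(logits, y)
        return loss, dlogits

    _directional_check(net, x, ce)


def test_embedder_backprop_and_unit_norm():
    rng = np.random.default_rng(1)
    net = build_embedder(
        tiny_spec(input_shape=(4, 16, 16, 1), n_classes=3, head="l2_embedding"), seed=3
    )
    x = rng.random((6, 4, 16, 16, 1)).astype(np.float32)
    emb = net.forward(x)
    assert np.abs(np.linalg.norm(emb, axis=1) - 1.0).max() < 1e-5

    # smooth surrogate objective: checks backprop through the whole stack
    # including L2 normalisation, without triplet-mining discontinuities
    c = np.random.default_rng(9).normal(size=emb.shape).astype(np.float32)

    def linear(embeddings):
        return float((embeddings * c).sum()), c

    # the normalised output is strongly curved in the weights, so the
    # finite-difference step must be small
    _directional_check(net, x, linear, tol=0.08, eps=3e-5)


def test_triplet_gradient_matches_finite_differences_at_fixed_mining():
    rng = np.random.default_rng(6)
    emb = rng.normal(size=(8, 4))
    labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
    loss, grad, n_pairs = triplet_semihard_loss(emb, labels, margin=1.0)
    assert n_pairs > 0
    d = rng.normal(size=emb.shape)
    eps = 1e-6  # small enough that the mined triplets do not change
    lp, _, _ = triplet_semihard_loss(emb + eps * d, labels, margin=1.0)
    lm, _, _ = triplet_semihard_loss(emb - eps * d, labels, margin=1.0)
    assert (lp - lm) / (2 * eps) == pytest.approx(float((grad * d).sum()), rel=1e-4)


def test_same_padding_output_lengths():
    # TF-style same padding: out = ceil(n / s) for every kernel
    for n in (3, 7, 12, 128):
        for k in (1, 3, 7):
            for s in (1, 2):
                out, pl, pr = _same_pad(n, k, s)
                assert out == -(-n // s)
                assert pl + pr == max((out - 1) * s + k - n, 0)


def test_batchnorm_normalises_and_tracks_running_stats():
    rng = np.random.default_rng(2)
    bn = BatchNorm(4)
    x = rng.normal(5.0, 3.0, size=(32, 6, 4)).astype(np.float32)
    y = bn.forward(x, training=True)
    assert np.abs(y.mean(axis=(0, 1))).max() < 1e-4
    assert np.abs(y.std(axis=(0, 1)) - 1.0).max() < 1e-3
    # eval mode uses the (first-batch-seeded) running statistics
    y_eval = bn.forward(x, training=False)
    np.testing.assert_allclose(y_eval, y, atol=1e-3)


def test_maxpool_partial_windows_and_backward_scatter():
    pool = MaxPool3D((1, 2, 2))
    x = np.arange(1 * 1 * 3 * 3 * 1, dtype=np.float32).reshape(1, 1, 3, 3, 1)
    y = pool.forward(x)
    # ceil semantics: 3 -> 2 windows per axis; maxima of each window
    assert y.shape == (1, 1, 2, 2, 1)
    np.testing.assert_array_equal(y[0, 0, :, :, 0], [[4, 5], [7, 8]])
    dout = np.ones_like(y)
    dx = pool.backward(dout)
    assert dx.shape == x.shape
    assert dx.sum() == dout.sum()  # every window routes its gradient once


def test_triplet_loss_zero_for_separated_classes_with_zero_margin():
    emb = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.float64)
    labels = np.array([0, 0, 1, 1])
    loss, grad, n_pairs = triplet_semihard_loss(emb, labels, margin=0.0)
    assert n_pairs == 4
    assert loss == 0.0
    assert np.all(grad == 0.0)


def test_triplet_loss_no_valid_pairs_is_zero():
    emb = np.eye(3)
    loss, grad, n_pairs = triplet_semihard_loss(emb, np.array([0, 1, 2]), margin=1.0)
    assert n_pairs == 0 and loss == 0.0
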