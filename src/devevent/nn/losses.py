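"""Loss functions with analytic gradients.

``softmax_cross_entropy`` is the classification objective (sparse integer
labels).  ``triplet_semihard_loss`` is the metric-learning objective: for
every anchor-positive pair within a batch it mines a semi-hard negative —
the nearest negative lying farther from the anchor than the positive — and
penalises ``max(0, d(a,p) - d(a,n) + margin)``.  If no semi-hard negative
exists the hardest (farthest) negative is used.  Distances are squared
Euclidean, which is monotone in distance and keeps the gradient exact.
"""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch.

    Returns ``(loss, dlogits, probs)``; ``dlogits`` is already divided by
    the batch size.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n, probs


def _pairwise_sq_dists(e: np.ndarray) -> np.ndarray:
    sq = (e * e).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (e @ e.T)
    return np.maximum(d, 0.0)


def triplet_semihard_loss(
    embeddings: np.ndarray, labels: np.ndarray, margin: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Semi-hard triplet loss averaged over anchor-positive pairs.

    Returns ``(loss, dembeddings, n_pairs)``.  ``n_pairs`` is 0 when the
    batch holds no valid anchor-positive pair with at least one negative,
    in which case the loss and gradient are zero.
    """
    n = embeddings.shape[0]
    d = _pairwise_sq_dists(embeddings)
    same = labels[:, None] == labels[None, :]
    grad = np.zeros_like(embeddings)
    total = 0.0
    n_pairs = 0
    for i in range(n):
        negs = np.flatnonzero(~same[i])
        if negs.size == 0:
            continue
        for j in np.flatnonzero(same[i]):
            if i == j:
                continue
            d_ap = d[i, j]
            harder = negs[d[i, negs] > d_ap]
            k = harder[np.argmin(d[i, harder])] if harder.size else negs[np.argmax(d[i, negs])]
            n_pairs += 1
            viol = d_ap - d[i, k] + margin
            if viol <= 0.0:
                continue
            total += viol
            a, p, ng = embeddings[i], embeddings[j], embeddings[k]
            grad[i] += 2.0 * (ng - p)
            grad[j] += 2.0 * (p - a)
            grad[k] += 2.0 * (a - ng)
    if n_pairs == 0:
        return 0.0, grad, 0
    return float(total / n_pairs), grad / n_pairs, n_pairs
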