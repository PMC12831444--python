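"""Independent reference implementations used to check the package.

Deliberately naive: explicit Python loops over the printed formulas, no
shared code with the vectorized implementations they verify.
"""

import numpy as np


def brute_force_supcon(z: np.ndarray, groups: np.ndarray, tau: float) -> float:
    """Double-loop evaluation of the supervised-contrastive loss (sum over anchors)."""
    n = len(z)
    total = 0.0
    for i in range(n):
        candidates = [a for a in range(n) if a != i]
        positives = [p for p in candidates if groups[p] == groups[i]]
        denom = sum(np.exp(float(z[i] @ z[a]) / tau) for a in candidates)
        inner = 0.0
        for p in positives:
            inner += np.log(np.exp(float(z[i] @ z[p]) / tau) / denom)
        total += -inner / len(positives)
    return total


def reference_infonce(z: np.ndarray, positive_of: dict[int, int], tau: float) -> float:
    """Standard InfoNCE cross-entropy with one positive per anchor.

    For each anchor, softmax over similarities to all other samples and take
    the negative log-probability of its positive.
    """
    n = len(z)
    total = 0.0
    for i in range(n):
        others = [a for a in range(n) if a != i]
        logits = np.array([float(z[i] @ z[a]) / tau for a in others])
        target = others.index(positive_of[i])
        logz = np.log(np.exp(logits - logits.max()).sum()) + logits.max()
        total += -(logits[target] - logz)
    return total


def concordance_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Binary ROC AUC by exhaustive pair enumeration (ties count half)."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_grouped_embeddings(rng: np.random.Generator, max_views: int = 32,
                              dim: int = 8):
    """Unit-norm embeddings with random groups, every anchor having a positive."""
    while True:
        n = int(rng.integers(4, max_views + 1))
        groups = rng.integers(0, max(2, n // 3), size=n)
        _, counts = np.unique(groups, return_counts=True)
        if counts.min() >= 2:
            break
    z = rng.standard_normal((n, dim))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    return z, groups
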