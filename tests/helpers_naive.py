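"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over points and pairs,
deliberately sharing no code with the package implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_entropy(p) -> float:
    total = 0.0
    for v in p:
        if v > 0:
            total -= v * math.log(v)
    return total


def naive_conditional_entropy(rows) -> float:
    return sum(naive_entropy(r) for r in rows) / len(rows)


def naive_marginal_entropy(rows) -> float:
    rows = np.asarray(rows, dtype=float)
    mean = rows.sum(axis=0) / len(rows)
    return naive_entropy(mean)


def naive_kl(p, q, eps=1e-12) -> float:
    total = 0.0
    for a, b in zip(p, q):
        total += a * (math.log(max(a, eps)) - math.log(max(b, eps)))
    return total


def naive_mse(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return total / len(a)


# ----------------------------------------------------------- validity indices
def _centroids(X, labels):
    k = int(max(labels)) + 1
    return [np.mean([x for x, l in zip(X, labels) if l == c], axis=0) for c in range(k)]


def _dist(a, b) -> float:
    return math.sqrt(sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)))


def naive_xie_beni(X, labels) -> float:
    v = _centroids(X, labels)
    compact = sum(_dist(x, v[l]) ** 2 for x, l in zip(X, labels))
    min_sep = min(
        _dist(v[i], v[j]) ** 2 for i in range(len(v)) for j in range(len(v)) if i < j
    )
    return compact / (len(X) * min_sep)


def naive_calinski_harabasz(X, labels) -> float:
    v = _centroids(X, labels)
    grand = np.mean(X, axis=0)
    k, n = len(v), len(X)
    counts = [sum(1 for l in labels if l == c) for c in range(k)]
    ssb = sum(counts[c] * _dist(v[c], grand) ** 2 for c in range(k))
    ssw = sum(_dist(x, v[l]) ** 2 for x, l in zip(X, labels))
    return (ssb / (k - 1)) / (ssw / (n - k))


def naive_c_index(X, labels) -> float:
    n = len(X)
    within, alldist = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(X[i], X[j])
            alldist.append(d)
            if labels[i] == labels[j]:
                within.append(d)
    nw = len(within)
    alldist.sort()
    s = sum(within)
    s_min = sum(alldist[:nw])
    s_max = sum(alldist[-nw:])
    return (s - s_min) / (s_max - s_min)


def naive_hartigan(X, labels) -> float:
    v = _centroids(X, labels)
    grand = np.mean(X, axis=0)
    k = len(v)
    counts = [sum(1 for l in labels if l == c) for c in range(k)]
    ssb = sum(counts[c] * _dist(v[c], grand) ** 2 for c in range(k))
    ssw = sum(_dist(x, v[l]) ** 2 for x, l in zip(X, labels))
    return math.log(ssb / ssw)


def naive_dunn(X, labels) -> float:
    n = len(X)
    inter, intra = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(X[i], X[j])
            (intra if labels[i] == labels[j] else inter).append(d)
    return min(inter) / max(intra)


def naive_mclain_rao(X, labels) -> float:
    n = len(X)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = _dist(X[i], X[j])
            (within if labels[i] == labels[j] else between).append(d)
    return (sum(within) / len(within)) / (sum(between) / len(between))


NAIVE_INDEX_FUNCS = {
    "xie_beni": naive_xie_beni,
    "calinski_harabasz": naive_calinski_harabasz,
    "c_index": naive_c_index,
    "hartigan": naive_hartigan,
    "dunn": naive_dunn,
    "mclain_rao": naive_mclain_rao,
}


def random_clustered_instance(rng, n_max=60, d_max=5, k_max=5):
    """A random labeled point set in which every cluster is non-empty
    and no two points coincide (keeps all six indices well-defined)."""
    k = int(rng.integers(2, k_max + 1))
    n = int(rng.integers(k + 2, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    centers = rng.normal(scale=4.0, size=(k, d))
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    X = centers[labels] + rng.normal(scale=0.7, size=(n, d))
    return X, labels
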