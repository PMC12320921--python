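"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package internals: set partitions
are enumerated directly, modularity is evaluated from its definition on the
positive/negative sub-networks, and clustering coefficients come from
explicit triple loops over node triples.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def set_partitions(n: int):
    """All set partitions of range(n) as membership vectors (restricted growth)."""

    def rec(prefix: list[int]) -> list[list[int]]:
        if len(prefix) == n:
            return [prefix]
        out = []
        m = max(prefix)
        for c in range(m + 2):
            out.extend(rec(prefix + [c]))
        return out

    return [np.asarray(p) for p in rec([0])]


def newman_modularity(w: np.ndarray, membership: np.ndarray) -> float:
    """Newman modularity of a non-negative weighted network, from definition."""
    v = w.sum()
    if v == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += (w[i, j] - k[i] * k[j] / v) / v
    return q


def asymmetric_signed_modularity(w: np.ndarray, membership: np.ndarray) -> float:
    """Q* = Q+ - [v-/(v+ + v-)] Q-, evaluated from its definition."""
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    qp = newman_modularity(wp, membership)
    qn = newman_modularity(wn, membership)
    if vp + vn == 0:
        return 0.0
    return qp - vn / (vp + vn) * qn


def _signed_q_vectorized(w: np.ndarray, membership: np.ndarray) -> float:
    """Same definition as :func:`asymmetric_signed_modularity`, without the
    python double loop (needed to exhaust partitions of 8 nodes quickly)."""
    same = membership[:, None] == membership[None, :]
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    q = 0.0
    if vp > 0:
        kp = wp.sum(axis=1)
        q += ((wp - np.outer(kp, kp) / vp)[same]).sum() / vp
    if vn > 0:
        kn = wn.sum(axis=1)
        q -= vn / (vp + vn) * ((wn - np.outer(kn, kn) / vn)[same]).sum() / vn
    return q


_PARTITION_CACHE: dict[int, list] = {}


def exhaustive_best_modularity(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum Q* over every partition of the nodes (feasible for n <= 8)."""
    n = w.shape[0]
    if n not in _PARTITION_CACHE:
        _PARTITION_CACHE[n] = set_partitions(n)
    best_q, best_p = -np.inf, None
    for p in _PARTITION_CACHE[n]:
        q = _signed_q_vectorized(w, p)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def brute_clustering_positive(w: np.ndarray) -> np.ndarray:
    """Positive weighted clustering by explicit triangle enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    c = np.zeros(n)
    for i in range(n):
        k = int(np.sum(w[i] > 0))
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def brute_clustering_signed(w: np.ndarray) -> np.ndarray:
    """Signed clustering by explicit enumeration of neighbour pairs."""
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        num = 0.0
        den = 0.0
        for j in range(n):
            for h in range(n):
                if j != h and j != i and h != i:
                    num += w[i, j] * w[i, h] * w[j, h]
                    den += abs(w[i, j] * w[i, h])
        if den > 0:
            c[i] = num / den
    return c


def random_signed_graph(
    rng: np.random.Generator, n: int, density: float = 0.5, signed: bool = True
) -> np.ndarray:
    """Random symmetric zero-diagonal weighted graph for oracle comparisons."""
    w = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if rng.random() < density:
            mag = rng.uniform(0.1, 1.0)
            if signed and rng.random() < 0.4:
                mag = -mag
            w[i, j] = w[j, i] = mag
    return w
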