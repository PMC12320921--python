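"""Segregation metrics on signed weighted networks.

Modularity uses Louvain-style greedy optimisation of the asymmetric signed
quality function

    Q* = Q+ - [v- / (v+ + v-)] * Q-

where Q+/Q- are Newman modularities of the positive/negative sub-networks and
v+/v- their total weights, so positive weights contribute fully while the
negative-weight penalty is down-weighted by the negative weight share.  For
all-non-negative matrices (SC) this reduces to standard weighted modularity.

Local clustering comes in a positive-weights form (geometric-mean triangle
intensity over max-normalised weights) and a signed generalisation in which a
node's clustering is the ratio of signed triangle products to the total
magnitude of its neighbour-pair weight products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ConnectomeMatrix

__all__ = [
    "PartitionedModularity",
    "signed_modularity_matrix",
    "partition_quality",
    "modularity_signed",
    "local_clustering_positive",
    "local_clustering_signed",
    "weighted_degree",
]


@dataclass
class PartitionedModularity:
    """Modularity statistic plus the partition achieving it."""

    Q: float
    partition: dict[str, int]
    n_restarts_used: int
    seed: int

    def membership(self, region_labels: list[str]) -> np.ndarray:
        return np.asarray([self.partition[r] for r in region_labels], dtype=int)


def _check_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10, rtol=0.0):
        raise ValueError("matrix must be symmetric")
    return w


def signed_modularity_matrix(w: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Modularity matrix B for the asymmetric signed quality function.

    B = B+/v+ - B-/(v+ + v-), with B± = W± - gamma * k± k±ᵀ / v± the Newman
    modularity matrices of the positive and negative sub-networks.  The sum of
    B over within-community pairs (self-pairs included) is Q*.
    """
    w = _check_square_symmetric(w)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    b = np.zeros_like(w)
    if vp > 0:
        kp = wp.sum(axis=1)
        b += (wp - gamma * np.outer(kp, kp) / vp) / vp
    if vn > 0:
        kn = wn.sum(axis=1)
        b -= (wn - gamma * np.outer(kn, kn) / vn) / (vp + vn)
    return b


def partition_quality(
    w: np.ndarray, membership: np.ndarray, gamma: float = 1.0
) -> float:
    """Q* of an explicit partition (community membership vector)."""
    b = signed_modularity_matrix(w, gamma)
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    return float(b[same].sum())


def _louvain_on_b(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain phases operating directly on a (aggregated) modularity matrix."""
    n = b.shape[0]
    mapping = np.arange(n)  # original node -> current super-node community
    bb = b.copy()
    while True:
        m = bb.shape[0]
        comm = np.arange(m)
        improved_any = False
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(m):
                ci = comm[i]
                row = bb[i]
                # B-weight from i to each community, self-pair excluded
                comm_sums = np.bincount(comm, weights=row, minlength=m)
                comm_sums[ci] -= row[i]
                current = comm_sums[ci]
                occupied = np.flatnonzero(np.bincount(comm, minlength=m) > 0)
                best_c, best_gain = ci, 0.0
                for c in occupied:
                    if c == ci:
                        continue
                    gain = 2.0 * (comm_sums[c] - current)
                    if gain > best_gain + 1e-14:
                        best_gain, best_c = gain, c
                if best_c != ci:
                    comm[i] = best_c
                    improved = True
                    improved_any = True
        uniq, comm = np.unique(comm, return_inverse=True)
        mapping = comm[mapping]
        if not improved_any or len(uniq) == bb.shape[0]:
            break
        # aggregate B by community
        k = len(uniq)
        agg = np.zeros((k, k))
        for a in range(k):
            sel_a = comm == a
            for c in range(a, k):
                sel_c = comm == c
                val = bb[np.ix_(sel_a, sel_c)].sum()
                agg[a, c] = val
                agg[c, a] = val
        bb = agg
    return mapping


def modularity_signed(
    m: ConnectomeMatrix | np.ndarray,
    resolution: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> PartitionedModularity:
    """Louvain optimisation of asymmetric signed modularity Q*.

    Runs ``n_restarts`` random-order Louvain passes and keeps the best Q*.
    Deterministic given ``seed``.  ``resolution`` is the gamma resolution
    parameter (1.0 recovers the classic quality function).
    """
    if isinstance(m, ConnectomeMatrix):
        w, labels = m.weights, m.region_labels
    else:
        w = _check_square_symmetric(m)
        labels = [f"ROI{i + 1:03d}" for i in range(w.shape[0])]
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    b = signed_modularity_matrix(w, resolution)
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_membership = np.zeros(w.shape[0], dtype=int)
    for _ in range(n_restarts):
        membership = _louvain_on_b(b, rng)
        same = membership[:, None] == membership[None, :]
        q = float(b[same].sum())
        if q > best_q:
            best_q = q
            best_membership = membership
    # contiguous community ids starting at 1
    _, best_membership = np.unique(best_membership, return_inverse=True)
    partition = {lab: int(c) + 1 for lab, c in zip(labels, best_membership)}
    return PartitionedModularity(best_q, partition, n_restarts, seed)


def local_clustering_positive(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient for non-negative networks.

    C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} / [k_i (k_i - 1)] with weights
    normalised by the network maximum (w' = w / max w) and k_i the binary
    degree; C_i = 0 for nodes with fewer than two neighbours.
    """
    w = m.weights if isinstance(m, ConnectomeMatrix) else _check_square_symmetric(m)
    if np.any(w < 0):
        raise ValueError("negative weights: use local_clustering_signed for FC")
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    wn = (w / wmax) ** (1.0 / 3.0)
    cyc3 = np.diagonal(wn @ wn @ wn)
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    c = np.zeros(w.shape[0])
    ok = denom > 0
    c[ok] = cyc3[ok] / denom[ok]
    return c


def local_clustering_signed(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Signed clustering coefficient (Costantini-Perugini generalisation).

    C_i = sum_{j != h} w_ij w_ih w_jh / sum_{j != h} |w_ij w_ih|; the numerator
    is the signed triangle intensity around i and the denominator the total
    magnitude of neighbour-pair products, so C_i lies in [-1, 1].  C_i = 0
    when the denominator vanishes (isolated node).
    """
    w = m.weights if isinstance(m, ConnectomeMatrix) else _check_square_symmetric(m)
    cyc3 = np.diagonal(w @ w @ w)  # diagonal zero removes j == h and i terms
    a = np.abs(w)
    s = a.sum(axis=1)
    denom = s**2 - (a**2).sum(axis=1)
    c = np.zeros(w.shape[0])
    ok = denom > 0
    c[ok] = cyc3[ok] / denom[ok]
    return c


def weighted_degree(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Average connection strength per region: d_i = sum_{j != i} w_ij / (N-1)."""
    w = m.weights if isinstance(m, ConnectomeMatrix) else _check_square_symmetric(m)
    n = w.shape[0]
    if n < 2:
        raise ValueError("weighted degree requires at least 2 regions")
    return w.sum(axis=1) / (n - 1)
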