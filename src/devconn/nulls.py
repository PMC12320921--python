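"""Degree- and weight-preserving randomizations of signed weighted networks.

Each null matrix preserves, per sign class, the binary degree sequence (via
double-edge swaps of the topology) and the exact multiset of edge weights,
while approximating each node's strength sequence through greedy rank-matching
of weights to rewired edges scored by the product of residual node strengths,
with periodic re-ranking.  Observed graph metrics are then compared against
the null ensemble with empirical tail proportions.

For dense signed matrices the two sign classes tile the complete graph, so a
within-class double-edge swap is realised as a position exchange with the
opposite class (the displaced opposite-sign edges take over the vacated
positions), which preserves the binary degree sequence of both classes
simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ConnectomeMatrix

__all__ = ["NullEnsemble", "generate_signed_null", "null_ensemble_pvalue"]


@dataclass
class NullEnsemble:
    """Ensemble of randomized matrices plus the generator settings."""

    matrices: list[np.ndarray]
    generator_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matrices)


def _rewire_sign_class(
    occ: np.ndarray, sign: int, swaps_per_edge: int, rng: np.random.Generator
) -> None:
    """Double-edge swaps of one sign class within the occupancy matrix.

    ``occ`` is a symmetric matrix over {-1, 0, +1} marking which sign class
    (if any) occupies each edge slot.  A swap of class edges (a,b),(c,d) to
    (a,d),(c,b) is accepted only when both target slots share the same status:
    either both empty, or both held by the opposite class, in which case the
    displaced opposite-class edges move to the vacated slots (an exchange that
    keeps both classes' degree sequences intact).
    """
    i, j = np.nonzero(np.triu(occ == sign, k=1))
    edges = list(zip(i.tolist(), j.tolist()))
    m = len(edges)
    if m < 2:
        return
    n_attempts = int(swaps_per_edge * m)
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        o1 = occ[a, d]
        o2 = occ[c, b]
        if o1 != o2 or o1 == sign:
            continue
        if o1 == 0:
            occ[a, b] = occ[b, a] = 0
            occ[c, d] = occ[d, c] = 0
        else:  # exchange with the opposite class
            occ[a, b] = occ[b, a] = -sign
            occ[c, d] = occ[d, c] = -sign
        occ[a, d] = occ[d, a] = sign
        occ[c, b] = occ[b, c] = sign
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))


def _assign_weights(
    n: int,
    edges: np.ndarray,
    weights: np.ndarray,
    strengths: np.ndarray,
    rerank_frequency: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Greedy rank-matching of weights to edges to approximate node strengths.

    The largest remaining weights go to the edges with the largest residual
    strength products; residual strengths are decremented as weights are
    placed and edge ranks recomputed every ``rerank_frequency`` share of the
    assignments.
    """
    w_sorted = np.sort(np.asarray(weights, float))[::-1]
    out = np.zeros((n, n))
    alive = np.ones(len(edges), dtype=bool)
    resid = strengths.astype(float).copy()
    batch = max(1, int(np.ceil(rerank_frequency * len(edges))))
    pos = 0
    while alive.any():
        idx = np.flatnonzero(alive)
        score = resid[edges[idx, 0]] * resid[edges[idx, 1]]
        order = idx[np.argsort(-score, kind="stable")]
        for e in order[:batch]:
            i, j = edges[e]
            w = w_sorted[pos]
            pos += 1
            out[i, j] = out[j, i] = w
            resid[i] -= w
            resid[j] -= w
            alive[e] = False
    return out


def generate_signed_null(
    m: ConnectomeMatrix | np.ndarray,
    n_nulls: int,
    seed: int = 0,
    swaps_per_edge: int = 10,
    rerank_frequency: float = 0.1,
) -> NullEnsemble:
    """Generate ``n_nulls`` signed degree/weight-preserving null matrices.

    The binary topology of each sign class is rewired with ``swaps_per_edge``
    double-edge swap attempts per edge, then the original weight multiset of
    each class is re-attached so node strengths are approximately preserved.
    Deterministic given ``seed``.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    w = m.weights if isinstance(m, ConnectomeMatrix) else np.asarray(m, float)
    if not np.allclose(w, w.T, atol=1e-10, rtol=0.0):
        raise ValueError("matrix must be symmetric")
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    sign_data = {}
    for sign in (1, -1):
        ws = np.where(sign * w > 0, sign * w, 0.0)
        iu = np.triu_indices(n, k=1)
        sign_data[sign] = (ws[iu][ws[iu] > 0], ws.sum(axis=1))
    base_occ = np.sign(w).astype(np.int8)
    nulls = []
    for _ in range(n_nulls):
        occ = base_occ.copy()
        for sign in (1, -1):
            _rewire_sign_class(occ, sign, swaps_per_edge, rng)
        null = np.zeros((n, n))
        for sign in (1, -1):
            weights, strengths = sign_data[sign]
            if weights.size == 0:
                continue
            i, j = np.nonzero(np.triu(occ == sign, k=1))
            edges = np.column_stack([i, j])
            null += sign * _assign_weights(
                n, edges, weights, strengths, rerank_frequency, rng
            )
        nulls.append(null)
    params = {
        "n_rewires_per_edge": swaps_per_edge,
        "weight_rerank_frequency": rerank_frequency,
        "seed": seed,
    }
    return NullEnsemble(nulls, params)


def null_ensemble_pvalue(observed: float, null_values, tail: str = "greater") -> float:
    """Empirical tail proportion of an observed metric within a null ensemble.

    Ties count as at least as extreme; the denominator is the number of null
    values, so the smallest resolvable nonzero p is 1/n (a zero count is best
    reported as p < 1/n).
    """
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ValueError("null value list is empty")
    if tail == "greater":
        return float(np.mean(nulls >= observed))
    if tail == "less":
        return float(np.mean(nulls <= observed))
    raise ValueError("tail must be 'greater' or 'less'")
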