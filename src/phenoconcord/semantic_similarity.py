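"""Semantic similarity between sub-score item clouds via optimal transport.

Each sub-score is represented by the cloud of its items' sentence-embedding
vectors on the unit sphere.  The semantic distance between two sub-scores is
the first-order Wasserstein (earth mover's) distance between the uniform
discrete measures on the two clouds, under the geodesic ground metric
``d(u, v) = arccos(<u, v>)``.  Distances are then min-max inverted into a
similarity in [0, 1] so that larger values mean greater semantic overlap.

The transport problem is solved exactly: for equal-size clouds the uniform
optimum is a permutation, found with the Hungarian algorithm; for unequal
sizes the full transportation linear program is solved with HiGHS.  No
entropic regularization is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse


def geodesic_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Great-circle distance in radians between two unit vectors.

    The inner product is clamped to [-1, 1] before arccos as a
    floating-point guard; inputs must be unit-norm to 1e-6.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("non-finite input vector")
    for name, x in (("u", u), ("v", v)):
        if abs(np.linalg.norm(x) - 1.0) > 1e-6:
            raise ValueError(f"{name} is not unit-norm")
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def geodesic_cost_matrix(cloud_a: np.ndarray, cloud_b: np.ndarray) -> np.ndarray:
    """Pairwise geodesic distances (radians) between two unit-vector clouds."""
    cloud_a = np.asarray(cloud_a, dtype=float)
    cloud_b = np.asarray(cloud_b, dtype=float)
    if cloud_a.shape[1] != cloud_b.shape[1]:
        raise ValueError(
            f"dimension mismatch: {cloud_a.shape[1]} vs {cloud_b.shape[1]}"
        )
    gram = np.clip(cloud_a @ cloud_b.T, -1.0, 1.0)
    return np.arccos(gram)


def wasserstein_distance(cloud_a: np.ndarray, cloud_b: np.ndarray) -> float:
    """Exact W1 distance between uniform measures on two embedding clouds.

    Equal-size clouds reduce to an assignment problem (the optimal uniform
    transport plan is a permutation by Birkhoff's theorem); unequal sizes
    solve the exact transportation LP.
    """
    cloud_a = np.atleast_2d(np.asarray(cloud_a, dtype=float))
    cloud_b = np.atleast_2d(np.asarray(cloud_b, dtype=float))
    if cloud_a.size == 0 or cloud_b.size == 0:
        raise ValueError("clouds must be nonempty")
    cost = geodesic_cost_matrix(cloud_a, cloud_b)
    n, m = cost.shape
    if n == m:
        rows, cols = scipy.optimize.linear_sum_assignment(cost)
        return float(cost[rows, cols].mean())
    return _transport_lp(cost)


def _transport_lp(cost: np.ndarray) -> float:
    """Solve min <C, P> s.t. P 1 = 1/n, P^T 1 = 1/m, P >= 0 with HiGHS."""
    n, m = cost.shape
    # row-sum constraints then column-sum constraints; drop one redundant row
    row_idx = np.repeat(np.arange(n), m)
    col_idx = n + np.tile(np.arange(m), n)
    data = np.ones(2 * n * m)
    rows = np.concatenate([row_idx, col_idx])
    cols = np.concatenate([np.arange(n * m), np.arange(n * m)])
    a_eq = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(n + m, n * m))
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = scipy.optimize.linprog(
        cost.ravel(), A_eq=a_eq[:-1], b_eq=b_eq[:-1], bounds=(0, None), method="highs"
    )
    if not res.success:  # pragma: no cover - LP on a feasible polytope
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


@dataclass
class SimilarityMatrix:
    """Pairwise sub-score semantic similarity with its raw-distance backing.

    ``similarity`` is ``1 - d / d_max`` with ``d_max`` the largest
    off-diagonal raw Wasserstein distance, so the most dissimilar pair maps
    to 0 and identical clouds to 1.  ``raw_distances`` (radians) is always
    retained so any other normalization can be applied post hoc.
    """

    subscores: list[str]
    raw_distances: pd.DataFrame
    similarity: pd.DataFrame

    def row(self, subscore_id: str) -> np.ndarray:
        """Off-diagonal similarity row w_i, in subscore order."""
        others = [s for s in self.subscores if s != subscore_id]
        return self.similarity.loc[subscore_id, others].to_numpy(dtype=float)


def similarity_matrix(clouds, subscores: list[str] | None = None) -> SimilarityMatrix:
    """All-pairs Wasserstein distances and min-max inverted similarities.

    Parameters
    ----------
    clouds
        An :class:`~phenoconcord.instruments_io.EmbeddingCloudSet` (or any
        object with a ``clouds`` dict attribute), or a plain dict mapping
        subscore id -> (n_items, D) unit-vector array.
    subscores
        Optional explicit ordering/subset; defaults to cloud insertion order.
    """
    cloud_map = clouds.clouds if hasattr(clouds, "clouds") else dict(clouds)
    order = subscores if subscores is not None else list(cloud_map)
    if len(order) < 2:
        raise ValueError("need at least 2 subscores")
    for s in order:
        if s not in cloud_map or np.asarray(cloud_map[s]).size == 0:
            raise ValueError(f"subscore {s!r} has no items")

    k = len(order)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = wasserstein_distance(cloud_map[order[i]], cloud_map[order[j]])
            dist[i, j] = dist[j, i] = d

    off = dist[~np.eye(k, dtype=bool)]
    d_max = off.max()
    sim = 1.0 - dist / d_max if d_max > 0 else np.ones_like(dist)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        subscores=list(order),
        raw_distances=pd.DataFrame(dist, index=order, columns=order),
        similarity=pd.DataFrame(sim, index=order, columns=order),
    )
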