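"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own graph algorithms: distances and
shortest-path counts come from boolean/integer matrix powers (the number of
walks of minimal length between two nodes equals the number of shortest
paths), betweenness from the path-count product identity, and eigenvector
centrality from a dense eigendecomposition.
"""

from __future__ import annotations

import numpy as np


def matrix_power_distances(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distances, shortest-path counts) via powers of the adjacency matrix.

    Unreachable pairs get distance inf and count 0; the diagonal is 0 / 1.
    """
    n = adj.shape[0]
    a = adj.astype(np.int64)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.eye(n, dtype=np.int64)
    power = np.eye(n, dtype=np.int64)
    for length in range(1, n):
        power = power @ a
        new = (power > 0) & np.isinf(dist)
        if not new.any():
            break
        dist[new] = length
        counts[new] = power[new]
    return dist, counts


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via sigma_st(v) = sigma_sv * sigma_vt."""
    n = adj.shape[0]
    dist, sigma = matrix_power_distances(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def brute_closeness(adj: np.ndarray) -> np.ndarray:
    """Closeness with the unreachable-distance = n substitution."""
    n = adj.shape[0]
    dist, _ = matrix_power_distances(adj)
    dist = np.where(np.isinf(dist), float(n), dist)
    return 1.0 / dist.sum(axis=1)


def brute_eigenvector(adj: np.ndarray) -> np.ndarray:
    """EC via dense eigendecomposition, replicating the component rule."""
    n = adj.shape[0]
    # connected components from reachability
    dist, _ = matrix_power_distances(adj)
    unassigned = set(range(n))
    comps = []
    while unassigned:
        s = min(unassigned)
        comp = sorted(v for v in unassigned if np.isfinite(dist[s, v]))
        comps.append(comp)
        unassigned -= set(comp)
    best = None
    for comp in comps:
        sub = adj[np.ix_(comp, comp)].astype(float)
        w, V = np.linalg.eigh(sub)
        lam = w[-1]
        if best is None or lam > best[0]:
            best = (lam, comp, V[:, -1])
    lam, comp, vec = best
    out = np.zeros(n)
    out[comp] = np.abs(vec)
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 0/1 adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return (adj | adj.T).astype(np.uint8)
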