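"""Density-thresholded binary graphs and centrality measures.

Connectivity matrices are reduced to undirected binary graphs by keeping a
fixed fraction of the strongest edges (largest signed Fisher z), which
matches connection density across participants and conditions regardless of
absolute connectivity level.  Four centralities are computed from their
definitions:

- closeness: CC(v) = 1 / sum_i d(v, i), unnormalized, with unreachable
  pairs assigned distance n (the node count) so CC stays finite on
  disconnected graphs and isolated nodes rank lowest;
- degree: edge count per node;
- betweenness: fractional shortest-path counting (Brandes accumulation),
  unnormalized, per unordered pair;
- eigenvector: leading adjacency eigenvector by power iteration; on
  disconnected graphs, computed on the component with the largest leading
  eigenvalue, zero elsewhere.

Edge ties at the density cut are broken by lexicographic node-pair order so
edge counts are exact and runs reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BinaryGraph",
    "DEFAULT_DENSITIES",
    "MEASURES",
    "threshold_binarize",
    "validate_density",
    "shortest_path_lengths",
    "closeness_centrality",
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "centrality_profile",
]

DEFAULT_DENSITIES = (0.20, 0.22, 0.24, 0.26, 0.28, 0.30)
MEASURES = ("closeness", "degree", "betweenness", "eigenvector")


@dataclass
class BinaryGraph:
    """Undirected binarized adjacency at a fixed edge density."""

    adjacency: np.ndarray       # (n, n) in {0, 1}, symmetric, zero diagonal
    density: float
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if self.node_ids is None:
            self.node_ids = np.arange(a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def threshold_binarize(z, density: float) -> BinaryGraph:
    """Keep the ``floor(density * n(n-1)/2)`` strongest edges, binarized.

    ``z`` is a square symmetric matrix or a :class:`ConnectivityMatrix`;
    strength is the signed value (not magnitude), ties at the cut broken by
    lexicographic (i, j) order.
    """
    z = np.asarray(getattr(z, "z", z), dtype=float)
    n = z.shape[0]
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n_pairs = n * (n - 1) // 2
    m = int(np.floor(density * n_pairs))
    if m == 0:
        raise ValueError(f"density {density} keeps zero of {n_pairs} edges")
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # strongest first; ties lexicographic
    keep = order[:m]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj = adj | adj.T
    return BinaryGraph(adjacency=adj, density=density)


def validate_density(
    graphs: list[BinaryGraph],
    node_frac: float = 0.85,
    participant_frac: float = 0.85,
) -> dict:
    """Check the 85/85 density-selection rule across participants.

    Passes iff at least ``participant_frac`` of the graphs have at least
    ``node_frac`` of their nodes with degree >= 1.
    """
    if not graphs:
        raise ValueError("no graphs to validate")
    per = []
    for g in graphs:
        frac = float((g.adjacency.sum(axis=0) >= 1).mean())
        per.append({"frac_connected_nodes": frac, "ok": frac >= node_frac})
    frac_participants = float(np.mean([p["ok"] for p in per]))
    return {
        "passed": frac_participants >= participant_frac,
        "frac_participants_ok": frac_participants,
        "node_frac": node_frac,
        "participant_frac": participant_frac,
        "per_graph": per,
    }


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """Unweighted BFS distances; unreachable pairs get distance n."""
    n = g.n_nodes
    adj = g.adjacency.astype(bool)
    reach = np.eye(n, dtype=bool)
    d = np.full((n, n), float(n))
    np.fill_diagonal(d, 0.0)
    for step in range(1, n):
        new = (reach @ adj) & ~reach
        if not new.any():
            break
        d[new] = step
        reach |= new
    return d


def closeness_centrality(g: BinaryGraph) -> np.ndarray:
    """CC(v) = 1 / sum of shortest distances to all other nodes."""
    d = shortest_path_lengths(g)
    sums = d.sum(axis=1)  # diagonal contributes 0
    return 1.0 / sums


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Number of connected edges per node."""
    return g.adjacency.sum(axis=0).astype(int)


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Unnormalized betweenness with fractional shortest-path counting.

    Brandes' accumulation over BFS shortest-path DAGs; for an undirected
    graph each unordered pair is counted once.
    """
    adj = g.adjacency
    n = g.n_nodes
    nbrs = [np.flatnonzero(adj[v]) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def _component_leading(adj: np.ndarray, comp: np.ndarray, tol: float, max_iter: int):
    """Power iteration for the Perron eigenpair of one component."""
    sub = adj[np.ix_(comp, comp)].astype(float)
    k = len(comp)
    if k == 1 or sub.sum() == 0:
        return 0.0, np.ones(k) / np.sqrt(k)
    x = np.ones(k) / np.sqrt(k)
    shifted = sub + np.eye(k)  # breaks period-2 oscillation on bipartite parts
    lam = 0.0
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    lam = float(x @ sub @ x)
    return lam, x


def eigenvector_centrality(
    g: BinaryGraph, tol: float = 1e-10, max_iter: int = 10000
) -> np.ndarray:
    """Leading-eigenvector centrality, unit Euclidean norm, nonnegative.

    For disconnected graphs the vector is computed on the connected
    component with the largest leading eigenvalue and set to zero elsewhere.
    An edgeless graph yields the zero vector with a warning.
    """
    n = g.n_nodes
    if g.n_edges == 0:
        warnings.warn("edgeless graph: eigenvector centrality undefined, returning zeros",
                      stacklevel=2)
        return np.zeros(n)
    n_comp, labels = connected_components(g.adjacency, directed=False)
    best = None
    for c in range(n_comp):
        comp = np.flatnonzero(labels == c)
        lam, vec = _component_leading(g.adjacency, comp, tol, max_iter)
        if best is None or lam > best[0]:
            best = (lam, comp, vec)
    _, comp, vec = best
    out = np.zeros(n)
    out[comp] = np.abs(vec)
    return out / np.linalg.norm(out)


_MEASURE_FUNCS = {
    "closeness": closeness_centrality,
    "degree": degree_centrality,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
}


def centrality_profile(
    matrices,
    densities=DEFAULT_DENSITIES,
    measures=MEASURES,
) -> pd.DataFrame:
    """Centralities per participant, condition, density and node.

    ``matrices`` is an iterable of :class:`ConnectivityMatrix`.  Returns a
    long table with columns
    ``participant, condition, density, node, measure, value``.
    """
    if isinstance(measures, str):
        measures = (measures,)
    frames = []
    for mat in matrices:
        n = mat.z.shape[0]
        for d in densities:
            g = threshold_binarize(mat, d)
            for measure in measures:
                vals = _MEASURE_FUNCS[measure](g)
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": mat.participant_id,
                            "condition": mat.condition,
                            "density": d,
                            "node": np.arange(n),
                            "measure": measure,
                            "value": np.asarray(vals, dtype=float),
                        }
                    )
                )
    if not frames:
        raise ValueError("no connectivity matrices supplied")
    return pd.concat(frames, ignore_index=True)
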