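"""Node definition from a thresholded scalar field on a vertex mesh.

A simplified surface-cluster-to-node algorithm: connected suprathreshold
components under mesh-edge connectivity are found, components with more than
``min_extent`` vertices are kept, local maxima at least ``min_separation``
mm apart (Euclidean, in vertex coordinates) seed the nodes, and each node is
grown down the statistic's gradients - a descending-value flood fill inside
its cluster - up to ``max_size`` vertices, with vertices claimed by an
earlier-grown node unavailable to later ones.

Additional pre-defined nodes (e.g. subcortical regions delineated in volume
space rather than on the mesh) can be injected by id.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ScalarMesh",
    "NodeSet",
    "find_clusters",
    "find_local_maxima",
    "grow_node",
    "extract_nodes",
    "make_grid_mesh",
    "save_mesh",
    "load_mesh",
]


@dataclass
class ScalarMesh:
    """Triangulated mesh with a per-vertex statistic and significance mask."""

    vertices: np.ndarray        # (V, 3) coordinates, mm
    triangles: np.ndarray       # (F, 3) vertex index triples
    values: np.ndarray          # (V,) statistic
    mask: np.ndarray            # (V,) bool, post-correction significance

    def __post_init__(self) -> None:
        V = len(self.vertices)
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= V):
            raise ValueError("triangles reference invalid vertices")
        if len(self.values) != V or len(self.mask) != V:
            raise ValueError("values and mask must be per-vertex")

    def vertex_neighbors(self) -> list[np.ndarray]:
        """Adjacency lists from triangle edges."""
        tri = self.triangles
        i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2], tri[:, 1], tri[:, 2], tri[:, 0]])
        j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0], tri[:, 0], tri[:, 1], tri[:, 2]])
        V = len(self.vertices)
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(V, V)).tocsr()
        adj.data[:] = 1
        return [adj.indices[adj.indptr[v]:adj.indptr[v + 1]] for v in range(V)]

    def _adjacency(self):
        tri = self.triangles
        i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
        j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
        V = len(self.vertices)
        m = coo_matrix((np.ones(len(i)), (i, j)), shape=(V, V))
        return m + m.T


@dataclass
class NodeSet:
    """Extracted nodes: id -> vertex membership, peak vertex and size."""

    nodes: dict = field(default_factory=dict)  # node_id -> dict(vertices, peak, size)

    def __len__(self) -> int:
        return len(self.nodes)

    def add(self, node_id, vertices, peak=None) -> None:
        vertices = np.asarray(sorted(vertices), dtype=int)
        for existing in self.nodes.values():
            if np.intersect1d(vertices, existing["vertices"]).size:
                raise ValueError("node vertex sets must be disjoint")
        self.nodes[node_id] = {"vertices": vertices, "peak": peak, "size": len(vertices)}

    def to_json(self, path) -> None:
        payload = {
            str(k): {
                "vertices": v["vertices"].tolist(),
                "peak": None if v["peak"] is None else int(v["peak"]),
                "size": v["size"],
            }
            for k, v in self.nodes.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NodeSet":
        with open(path) as fh:
            payload = json.load(fh)
        ns = cls()
        for k, v in payload.items():
            ns.add(k, v["vertices"], v["peak"])
        return ns


def find_clusters(mesh: ScalarMesh, min_extent: int = 100) -> list[np.ndarray]:
    """Connected suprathreshold components with extent strictly > min_extent.

    Components are taken under mesh-edge connectivity among masked vertices
    and returned as sorted vertex-index arrays, largest first (ties by lowest
    vertex index).  An empty mask yields an empty list.
    """
    masked = np.flatnonzero(mesh.mask)
    if masked.size == 0:
        return []
    sub = mesh._adjacency().tocsr()[masked][:, masked]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = [masked[labels == c] for c in range(n_comp)]
    clusters = [np.sort(c) for c in clusters if len(c) > min_extent]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def find_local_maxima(
    mesh: ScalarMesh, cluster: np.ndarray, min_separation: float = 25.0
) -> list[int]:
    """Greedy peak selection within a cluster.

    Candidates are visited in descending statistic order (ties by lower
    vertex index); a candidate is kept iff its Euclidean distance to every
    already-kept peak is at least ``min_separation`` mm.
    """
    cluster = np.asarray(cluster)
    order = cluster[np.lexsort((cluster, -mesh.values[cluster]))]
    peaks: list[int] = []
    for v in order:
        xyz = mesh.vertices[v]
        if all(np.linalg.norm(xyz - mesh.vertices[p]) >= min_separation for p in peaks):
            peaks.append(int(v))
    return peaks


def grow_node(
    mesh: ScalarMesh,
    cluster: np.ndarray,
    peak: int,
    max_size: int = 600,
    claimed=None,
    neighbors=None,
) -> np.ndarray:
    """Region-grow a node from a peak by descending-value flood fill.

    Starting at the peak, repeatedly add the unclaimed in-cluster frontier
    vertex with the highest statistic (ties by lower vertex index), stopping
    at ``max_size`` vertices or when the reachable cluster is exhausted.
    ``claimed`` (a set, mutated in place) makes vertices taken by earlier
    nodes unavailable.
    """
    cluster_set = set(int(v) for v in cluster)
    peak = int(peak)
    if peak not in cluster_set:
        raise ValueError("peak vertex is not part of the cluster")
    claimed = claimed if claimed is not None else set()
    if neighbors is None:
        neighbors = mesh.vertex_neighbors()
    grown: list[int] = []
    seen = set()
    heap = [(-float(mesh.values[peak]), peak)]
    seen.add(peak)
    while heap and len(grown) < max_size:
        _, v = heapq.heappop(heap)
        if v in claimed:
            continue
        grown.append(v)
        claimed.add(v)
        for nb in neighbors[v]:
            nb = int(nb)
            if nb in cluster_set and nb not in seen and nb not in claimed:
                seen.add(nb)
                heapq.heappush(heap, (-float(mesh.values[nb]), nb))
    return np.array(sorted(grown), dtype=int)


def extract_nodes(
    mesh: ScalarMesh,
    min_extent: int = 100,
    min_separation: float = 25.0,
    max_size: int = 600,
    predefined: dict | None = None,
) -> NodeSet:
    """Full cluster-to-node chain: clusters, peaks, grown regions.

    Within each cluster, peaks are grown in descending peak-value order
    (ties by lower vertex index) so earlier nodes claim shared territory.
    ``predefined`` maps extra node ids to explicit vertex arrays injected
    verbatim (e.g. volume-space regions such as the hippocampi).
    """
    ns = NodeSet()
    neighbors = mesh.vertex_neighbors()
    idx = 0
    for cluster in find_clusters(mesh, min_extent):
        peaks = find_local_maxima(mesh, cluster, min_separation)
        claimed: set = set()
        for peak in sorted(peaks, key=lambda p: (-mesh.values[p], p)):
            grown = grow_node(mesh, cluster, peak, max_size, claimed, neighbors)
            if grown.size:
                ns.add(f"node_{idx:03d}", grown, peak)
                idx += 1
    for node_id, vertices in (predefined or {}).items():
        ns.add(node_id, vertices)
    return ns


def save_mesh(mesh: ScalarMesh, path) -> None:
    """Write a mesh as OFF-like text with per-vertex value/mask columns.

    Header line ``VOFF n_vertices n_triangles``; then one line per vertex
    (``x y z value mask``) and one per triangle (``a b c``).
    """
    with open(path, "w") as fh:
        fh.write(f"VOFF {len(mesh.vertices)} {len(mesh.triangles)}\n")
        for (x, y, z), v, m in zip(mesh.vertices, mesh.values, mesh.mask):
            fh.write(f"{x:.8g} {y:.8g} {z:.8g} {v:.8g} {int(m)}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"{a} {b} {c}\n")


def load_mesh(path) -> ScalarMesh:
    """Read a mesh written by :func:`save_mesh`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[0] != "VOFF":
            raise ValueError(f"{path}: not a VOFF mesh file")
        nv, nt = int(header[1]), int(header[2])
        vrows = [fh.readline().split() for _ in range(nv)]
        trows = [fh.readline().split() for _ in range(nt)]
    vertices = np.array([[float(x) for x in r[:3]] for r in vrows])
    values = np.array([float(r[3]) for r in vrows])
    mask = np.array([bool(int(r[4])) for r in vrows])
    triangles = np.array([[int(x) for x in r] for r in trows], dtype=int)
    if triangles.size == 0:
        triangles = np.empty((0, 3), dtype=int)
    return ScalarMesh(vertices=vertices, triangles=triangles, values=values, mask=mask)


def make_grid_mesh(nx: int, ny: int, spacing: float = 1.0) -> ScalarMesh:
    """Regular triangulated plane grid - a convenient test/demo substrate."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    vertices = np.column_stack(
        [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(nx * ny)]
    )
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return ScalarMesh(
        vertices=vertices,
        triangles=np.array(tris, dtype=int),
        values=np.zeros(nx * ny),
        mask=np.zeros(nx * ny, dtype=bool),
    )
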