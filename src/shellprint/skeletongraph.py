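"""Skeletonization and the feature-point graph.

A binary line map is thinned to 1-pixel centerlines; bifurcation and
crossover pixels (three or more skeleton neighbors among the 8-adjacent
pixels) are clustered into candidate feature points; the centerline
segments between clusters become graph edges carrying their pixel paths.
Iteratively deleting degree-1 vertices leaves the 2-core, the subgraph in
which every cyclic structure lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "SkeletonGraph",
    "FeaturePointSet",
    "skeletonize",
    "detect_feature_points",
    "build_graph",
    "prune_to_cycle_graph",
]

_NEIGH_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


class SkeletonGraph:
    """Undirected multigraph of feature points and centerline paths.

    Nodes carry a float ``(row, col)`` position and a ``kind`` in
    {"bifurcation", "crossover", "endpoint", "unknown"}; edges carry the
    ordered pixel ``path`` (float array, endpoints at the node positions)
    and its arc ``length`` (unit steps, sqrt(2) for diagonal moves).
    Parallel edges are kept: two ribs crossed twice by the same ring are a
    legitimate 2-cycle of distinct paths.
    """

    def __init__(self) -> None:
        self.g = nx.MultiGraph()

    # -- construction ------------------------------------------------
    def add_node(self, nid: int, pos, kind: str = "unknown") -> None:
        self.g.add_node(int(nid), pos=np.asarray(pos, dtype=float), kind=kind)

    def add_edge(self, u: int, v: int, path=None, length: float | None = None) -> int:
        if path is None:
            path = np.stack([self.pos(u), self.pos(v)])
        path = np.asarray(path, dtype=float)
        if length is None:
            length = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
        return self.g.add_edge(int(u), int(v), path=path, length=float(length))

    # -- queries -----------------------------------------------------
    def pos(self, nid: int) -> np.ndarray:
        return self.g.nodes[nid]["pos"]

    def kind(self, nid: int) -> str:
        return self.g.nodes[nid]["kind"]

    @property
    def nodes(self):
        return self.g.nodes

    @property
    def edges(self):
        return self.g.edges

    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def degree(self, nid: int) -> int:
        return self.g.degree(nid)

    def edge_length(self, u: int, v: int, key: int) -> float:
        return self.g.edges[u, v, key]["length"]

    def edge_path(self, u: int, v: int, key: int) -> np.ndarray:
        """Pixel path oriented from u to v."""
        data = self.g.edges[u, v, key]
        path = data["path"]
        if np.linalg.norm(path[0] - self.pos(u)) <= np.linalg.norm(
            path[-1] - self.pos(u)
        ):
            return path
        return path[::-1]

    def edge_direction(self, u: int, v: int, key: int, probe_frac: float = 0.3) -> np.ndarray:
        """Unit outgoing direction of edge (u, v, key) at node u.

        Uses the point a fixed *fraction* of the arc length along the
        stored path rather than the chord, so curved arcs and parallel
        edges get distinct directions and the direction is invariant to
        uniform rescaling of the coordinates.
        """
        path = self.edge_path(u, v, key)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        target = probe_frac * cum[-1]
        idx = int(np.searchsorted(cum, target))
        idx = max(1, min(idx, len(path) - 1))
        d = path[idx] - path[0]
        n = np.linalg.norm(d)
        if n == 0:
            d = self.pos(v) - self.pos(u)
            n = np.linalg.norm(d) or 1.0
        return d / n

    def incident(self, nid: int):
        """List of (u, v, key) with u == nid (self-loops appear twice)."""
        out = []
        for u, v, k in self.g.edges(nid, keys=True):
            out.append((nid, v if u == nid else u, k))
            if u == v:
                out.append((nid, nid, k))
        return out

    def copy(self) -> "SkeletonGraph":
        out = SkeletonGraph()
        out.g = self.g.copy()
        return out

    def to_graphml(self, path) -> None:
        """GraphML export: node row/col/kind, edge length (paths omitted)."""
        out = nx.MultiGraph()
        for nid, data in self.g.nodes(data=True):
            out.add_node(
                nid,
                row=float(data["pos"][0]),
                col=float(data["pos"][1]),
                kind=data["kind"],
            )
        for u, v, k, data in self.g.edges(keys=True, data=True):
            out.add_edge(u, v, key=k, length=float(data["length"]))
        nx.write_graphml(out, path)

    def transformed(self, linear=None, translation=None) -> "SkeletonGraph":
        """Apply an affine map to all coordinates (positions and paths)."""
        A = np.eye(2) if linear is None else np.asarray(linear, dtype=float)
        t = np.zeros(2) if translation is None else np.asarray(translation, dtype=float)
        out = SkeletonGraph()
        for nid, data in self.g.nodes(data=True):
            out.add_node(nid, A @ data["pos"] + t, data["kind"])
        for u, v, k, data in self.g.edges(keys=True, data=True):
            path = data["path"] @ A.T + t
            out.add_edge(u, v, path=path)
        return out


@dataclass
class FeaturePointSet:
    """Candidate feature points: cluster centers plus the pixel clusters."""

    points: np.ndarray            # (m, 2) cluster centers, float
    labels: np.ndarray            # int image, 0 = background, i = cluster i
    n_clusters: int

    def __len__(self) -> int:
        return self.n_clusters


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving morphological thinning to 1-px centerlines."""
    mask = np.asarray(mask, dtype=bool)
    return _skimage_skeletonize(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    return ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")


def detect_feature_points(skel: np.ndarray) -> FeaturePointSet:
    """Bifurcation/crossover candidates on a thinned skeleton.

    Pixels with at least three 8-adjacent skeleton pixels are labeled;
    8-connected clusters of labeled pixels are collapsed to their center
    of mass (thinning can smear one junction over a few pixels).
    """
    skel = np.asarray(skel, dtype=bool)
    counts = _neighbor_counts(skel)
    junction = skel & (counts > 2)
    labels, n = ndimage.label(junction, structure=np.ones((3, 3)))
    if n == 0:
        return FeaturePointSet(np.zeros((0, 2)), labels, 0)
    centers = np.asarray(ndimage.center_of_mass(junction, labels, range(1, n + 1)))
    return FeaturePointSet(centers, labels, n)


def _order_chain(pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a 1-px-wide segment by walking it."""
    pset = set(pixels)
    if len(pixels) == 1:
        return list(pixels)
    nbrs = {
        p: [q for dr, dc in _NEIGH_OFFSETS if (q := (p[0] + dr, p[1] + dc)) in pset]
        for p in pixels
    }
    ends = [p for p in pixels if len(nbrs[p]) <= 1]
    start = min(ends) if ends else min(pixels)
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid diagonal shortcuts
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        order.append(cur)
        seen.add(cur)
    return order


def _adjacent_cluster(pix: tuple[int, int], labels: np.ndarray) -> int:
    """Label of a feature cluster 8-adjacent to pix, or 0."""
    r0, c0 = pix
    for dr, dc in _NEIGH_OFFSETS:
        r, c = r0 + dr, c0 + dc
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]:
            if labels[r, c]:
                return int(labels[r, c])
    return 0


def build_graph(
    skel: np.ndarray,
    candidates: FeaturePointSet,
    min_spur: float = 5.0,
) -> SkeletonGraph:
    """Trace centerline paths between candidate clusters into a graph.

    Segments touching a cluster at only one end become dangling edges
    terminating in fresh degree-1 "endpoint" nodes (pruned later);
    dangling edges shorter than ``min_spur`` pixels are treated as
    thinning spurs and dropped outright.
    """
    skel = np.asarray(skel, dtype=bool)
    labels = candidates.labels
    g = SkeletonGraph()
    for i in range(candidates.n_clusters):
        g.add_node(i + 1, candidates.points[i])

    seg_mask = skel & (labels == 0)
    seg_labels, n_segs = ndimage.label(seg_mask, structure=np.ones((3, 3)))
    next_id = candidates.n_clusters + 1
    for s in range(1, n_segs + 1):
        pix = list(zip(*np.nonzero(seg_labels == s)))
        chain = _order_chain(pix)
        a = _adjacent_cluster(chain[0], labels)
        b = _adjacent_cluster(chain[-1], labels)
        pts = np.asarray(chain, dtype=float)
        if a and b:
            path = np.vstack([g.pos(a)[None], pts, g.pos(b)[None]])
            g.add_edge(a, b, path=path)
        elif a or b:
            node = a or b
            if not a:
                chain = chain[::-1]
                pts = pts[::-1]
            path = np.vstack([g.pos(node)[None], pts])
            length = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
            if length < min_spur:
                continue
            g.add_node(next_id, pts[-1], kind="endpoint")
            g.add_edge(node, next_id, path=path)
            next_id += 1
        else:
            if len(chain) >= 8 and max(
                abs(chain[0][0] - chain[-1][0]), abs(chain[0][1] - chain[-1][1])
            ) <= 1:
                # isolated closed loop: keep as a self-loop on one pixel
                g.add_node(next_id, pts[0], kind="unknown")
                path = np.vstack([pts, pts[0][None]])
                g.add_edge(next_id, next_id, path=path)
                next_id += 1
            # isolated open fragments carry no cycle information: drop

    _assign_kinds(g)
    return g


def _assign_kinds(g: SkeletonGraph) -> None:
    for nid in list(g.nodes):
        if g.kind(nid) == "endpoint":
            continue
        deg = g.degree(nid)
        if deg == 3:
            g.nodes[nid]["kind"] = "bifurcation"
        elif deg >= 4:
            g.nodes[nid]["kind"] = "crossover"


def prune_to_cycle_graph(g: SkeletonGraph) -> SkeletonGraph:
    """Iteratively delete degree-1 vertices: the (unique) 2-core.

    A vertex can sit on a cycle only if at least two edges survive at it,
    so repeated removal of degree-1 vertices leaves exactly the cyclic
    part of the network.  Self-loops count 2 toward degree.
    """
    out = g.copy()
    while True:
        leaves = [n for n in out.nodes if out.degree(n) <= 1]
        if not leaves:
            break
        out.g.remove_nodes_from(leaves)
    _assign_kinds(out)
    return out
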