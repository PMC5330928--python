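"""Cyclic structures: extraction, description, and matching.

A cyclic structure is a small closed loop (3-6 feature points) of the
rib/ring network — the minutiae-like signature used to re-identify an
individual shell.  Extraction uses the Space-based Depth-First Search
(SDFS): a depth-first traversal of the 2-core that, at every feature
point, continues along the neighbor making the tightest consistent turn.
The turn ordering comes from the sign and angle of the 2-D cross product
between the incoming and outgoing edge vectors, so each traversal closes
the smallest face-like cycle through its starting edge.  On a planar
embedding this is exactly face tracing, and the interior faces form a
minimum cycle basis — which is the independent oracle used in tests.

Each structure is described by a scale- and rotation-invariant vector of
6n entries (cycle sizes n = 3..6 give 18, 24, 30, 36 dimensions):

* n cycle-edge lengths, normalized by their sum (L_i / sum L_i),
* 4n branch angles — at each point the consecutive angular gaps between
  its incident edge directions, up to four per point (a bifurcation has
  three, a crossover four); absent slots are zero,
* n adjacent-edge (corner) angles between consecutive cycle edges,

with every angle divided by 360 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .skeletongraph import SkeletonGraph

__all__ = [
    "CyclicStructure",
    "MatchResult",
    "sdfs_cycles",
    "min_cycle_basis_oracle",
    "describe_cycle",
    "feature_dimension",
    "match_structures",
    "align_matched_pair",
]

DirectedEdge = tuple[int, int, int]  # (tail, head, key)


@dataclass
class CyclicStructure:
    """An oriented simple cycle of feature points in a skeleton graph."""

    node_ids: tuple[int, ...]
    edge_keys: tuple[int, ...]     # key of edge node_ids[i] -> node_ids[i+1]
    positions: np.ndarray          # (n, 2), aligned with node_ids

    @property
    def n(self) -> int:
        return len(self.node_ids)


def feature_dimension(n: int) -> int:
    """Descriptor dimension for an n-point structure: n + 4n + n = 6n."""
    if not 3 <= n <= 6:
        raise ValueError("cycle size must be between 3 and 6")
    return 6 * n


# ---------------------------------------------------------------------------
# SDFS extraction


def _direction_angle(vec: np.ndarray) -> float:
    """Angle of a (row, col) vector, radians, CCW from +col."""
    return float(np.arctan2(vec[0], vec[1]))


def _ccw_gap(a: float, b: float) -> float:
    """Positive CCW angle from direction a to direction b, in (0, 2*pi]."""
    gap = (b - a) % (2.0 * np.pi)
    return gap if gap > 0 else 2.0 * np.pi


def _next_directed_edge(g: SkeletonGraph, edge: DirectedEdge) -> DirectedEdge:
    """Tightest-turn successor of a directed edge.

    Arriving at ``head`` along ``edge``, the successor leaves ``head``
    through the incident edge whose outgoing direction makes the smallest
    strictly positive CCW turn from the reversed incoming direction; the
    turn sense of each candidate is the sign of the cross product of the
    incoming and outgoing vectors.  The reverse of the incoming edge
    itself is the last resort (gap 2*pi), so dead ends bounce back.
    """
    tail, head, key = edge
    back_dir = g.edge_direction(head, tail, key)
    back_angle = _direction_angle(back_dir)
    best: DirectedEdge | None = None
    best_key = None
    for (u, w, k) in g.incident(head):
        out_dir = g.edge_direction(head, w, k)
        gap = _ccw_gap(back_angle, _direction_angle(out_dir))
        if w == tail and k == key and head != tail:
            gap = 2.0 * np.pi  # immediate backtrack only if nothing else
        cand_key = (gap, g.edge_length(head, w, k), w, k)
        if best_key is None or cand_key < best_key:
            best_key = cand_key
            best = (head, w, k)
    assert best is not None
    return best


def _polygon_area(points: np.ndarray) -> float:
    """Shoelace signed area with (x, y) = (col, row)."""
    x = points[:, 1]
    y = points[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _canonical_cycle(nodes: tuple[int, ...], keys: tuple[int, ...]):
    """Canonical form of an oriented cycle up to rotation and reflection."""
    n = len(nodes)
    seqs = []
    for rev in (False, True):
        if rev:
            nd = tuple(reversed(nodes))
            ky = tuple(reversed(keys[-1:] + keys[:-1]))
        else:
            nd, ky = nodes, keys
        for s in range(n):
            seqs.append((nd[s:] + nd[:s], ky[s:] + ky[:s]))
    return min(seqs)


def sdfs_cycles(g: SkeletonGraph, max_cycle_len: int = 6) -> list[CyclicStructure]:
    """All face-like cycles of length 3..max_cycle_len in the 2-core.

    Every directed edge is traversed once under the tightest-turn
    successor rule; the resulting orbits are the faces of the embedding
    given by the node coordinates.  Orbits with repeated nodes (bridges,
    outer boundaries of dumbbell components) are discarded, and of the two
    orientations of each face only one survives deduplication.  The outer
    face of a component is removed by its opposite traversal orientation
    (signed polygon area), never by length alone, so a lone hexagon still
    yields exactly one structure.
    """
    if not 3 <= max_cycle_len <= 6:
        raise ValueError("max_cycle_len must be in 3..6")
    directed: list[DirectedEdge] = []
    for u, v, k in g.g.edges(keys=True):
        directed.append((u, v, k))
        directed.append((v, u, k))
    used: set[DirectedEdge] = set()
    raw: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    for start in directed:
        if start in used:
            continue
        orbit = [start]
        used.add(start)
        cur = start
        closed = False
        while True:
            cur = _next_directed_edge(g, cur)
            if cur == start:
                closed = True
                break
            if cur in used:
                break  # degenerate geometry broke the rotation system
            orbit.append(cur)
            used.add(cur)
        if not closed:
            continue
        nodes = tuple(e[0] for e in orbit)
        keys = tuple(e[2] for e in orbit)
        raw.append((nodes, keys))

    seen: set[tuple] = set()
    out: list[CyclicStructure] = []
    for nodes, keys in raw:
        n = len(nodes)
        if not 3 <= n <= max_cycle_len:
            continue
        if len(set(nodes)) != n:
            continue
        pos = np.stack([g.pos(nid) for nid in nodes])
        if _polygon_area(pos) >= 0:
            # under the tightest-CCW-turn rule interior faces come out
            # with negative shoelace area in the (row, col) frame; the
            # opposite orientation traces the outer boundary, so keep
            # only the negative-area orbits
            continue
        canon = _canonical_cycle(nodes, keys)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(CyclicStructure(node_ids=nodes, edge_keys=keys, positions=pos))
    out.sort(key=lambda c: (c.n, c.node_ids))
    return out


# ---------------------------------------------------------------------------
# Minimum-cycle-basis oracle (testing only)


def min_cycle_basis_oracle(g: SkeletonGraph) -> list[list[int]]:
    """Minimum cycle basis of the unweighted graph, via an exact method.

    Parallel edges are split with auxiliary midpoint nodes (negative ids)
    before calling the standard algorithm; auxiliary nodes are removed
    from the returned cycles.  Used as an independent oracle for SDFS.
    """
    simple = nx.Graph()
    aux = -1
    for nid in g.nodes:
        simple.add_node(nid)
    seen_pairs: dict[tuple[int, int], int] = {}
    for u, v, k in g.g.edges(keys=True):
        a, b = min(u, v), max(u, v)
        if u == v:
            simple.add_edge(u, aux)
            simple.add_edge(aux, aux - 1)
            simple.add_edge(aux - 1, u)
            aux -= 2
        elif (a, b) in seen_pairs or simple.has_edge(u, v):
            simple.add_edge(u, aux)
            simple.add_edge(aux, v)
            aux -= 1
        else:
            simple.add_edge(u, v)
            seen_pairs[(a, b)] = k
    basis = []
    for cyc in nx.minimum_cycle_basis(simple):
        basis.append([n for n in cyc if n >= 0])
    return basis


# ---------------------------------------------------------------------------
# Description


def _sorted_incident_directions(
    full: SkeletonGraph, nid: int, cycle_edges: set[tuple[int, int]]
) -> tuple[list[float], list[float], list[bool]]:
    """Incident edge directions at nid sorted CCW.

    Returns (angles, lengths, is_cycle_edge); at points with more than
    four incident edges the two cycle edges plus the longest branches are
    kept (four total).
    """
    entries = []
    for (u, w, k) in full.incident(nid):
        d = full.edge_direction(nid, w, k)
        ang = _direction_angle(d)
        is_cyc = (nid, w, k) in cycle_edges or (w, nid, k) in cycle_edges
        entries.append((ang, full.edge_length(nid, w, k), is_cyc))
    if len(entries) > 4:
        cyc = [e for e in entries if e[2]]
        branches = sorted((e for e in entries if not e[2]), key=lambda e: -e[1])
        entries = cyc + branches[: max(0, 4 - len(cyc))]
    entries.sort(key=lambda e: e[0])
    return (
        [e[0] for e in entries],
        [e[1] for e in entries],
        [e[2] for e in entries],
    )


def _branch_angle_slots(
    full: SkeletonGraph,
    nid: int,
    out_edge: tuple[int, int, int],
) -> list[float]:
    """Up to four consecutive angular gaps at a feature point, degrees.

    The gap list starts at the outgoing cycle edge so the slot order is a
    function of the structure itself, not of the image orientation.
    """
    cyc_marker = {(out_edge[0], out_edge[1], out_edge[2])}
    entries = []
    for (u, w, k) in full.incident(nid):
        d = full.edge_direction(nid, w, k)
        entries.append(((u, w, k), _direction_angle(d), full.edge_length(nid, w, k)))
    if len(entries) > 4:
        keep = [e for e in entries if e[0] in cyc_marker]
        # always retain the outgoing cycle edge, then the longest others
        rest = sorted((e for e in entries if e[0] not in cyc_marker), key=lambda e: -e[2])
        entries = keep + rest[: 4 - len(keep)]
    entries.sort(key=lambda e: e[1])
    angles = [e[1] for e in entries]
    ids = [e[0] for e in entries]
    try:
        start = ids.index((out_edge[0], out_edge[1], out_edge[2]))
    except ValueError:
        start = 0
    d = len(angles)
    gaps = []
    for i in range(d):
        a = angles[(start + i) % d]
        b = angles[(start + i + 1) % d]
        gaps.append(np.degrees(_ccw_gap(a, b)) if d > 1 else 360.0)
    gaps = gaps[:4] + [0.0] * max(0, 4 - len(gaps))
    return gaps


def _corner_angle(prev_pos, cur_pos, next_pos) -> float:
    """Unsigned angle at cur between the two cycle edges, degrees."""
    a = prev_pos - cur_pos
    b = next_pos - cur_pos
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    cosv = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def describe_cycle(c: CyclicStructure, g: SkeletonGraph) -> np.ndarray:
    """Scale/rotation-invariant 6n descriptor of a cyclic structure.

    ``g`` should be the full (unpruned) graph so external branches at the
    cycle points contribute their angular gaps.  The cycle is first
    re-oriented to positive signed area; among the n possible starting
    points the rotation giving the lexicographically smallest vector is
    the canonical one, making the descriptor independent of how (and in
    which image orientation) the cycle was traversed.
    """
    n = c.n
    nodes = list(c.node_ids)
    keys = list(c.edge_keys)
    if _polygon_area(c.positions) < 0:
        nodes = nodes[::-1]
        keys = (keys[-1:] + keys[:-1])[::-1]
    pos = np.stack([g.pos(nid) for nid in nodes])

    cycle_edge_set = {
        (nodes[i], nodes[(i + 1) % n], keys[i]) for i in range(n)
    } | {(nodes[(i + 1) % n], nodes[i], keys[i]) for i in range(n)}

    lengths = np.array(
        [g.edge_length(nodes[i], nodes[(i + 1) % n], keys[i]) for i in range(n)]
    )
    total = lengths.sum()
    if total <= 0:
        raise ValueError("degenerate cycle with zero total length")
    lnorm = lengths / total

    branch = np.zeros((n, 4))
    for i in range(n):
        out_edge = (nodes[i], nodes[(i + 1) % n], keys[i])
        branch[i] = _branch_angle_slots(g, nodes[i], out_edge)
    branch /= 360.0

    corners = np.array(
        [
            _corner_angle(pos[i - 1], pos[i], pos[(i + 1) % n])
            for i in range(n)
        ]
    ) / 360.0

    best = None
    for s in range(n):
        vec = np.concatenate(
            [
                np.roll(lnorm, -s),
                np.roll(branch, -s, axis=0).ravel(),
                np.roll(corners, -s),
            ]
        )
        key = tuple(np.round(vec, 9))
        if best is None or key < best[0]:
            best = (key, vec)
    return best[1]


# ---------------------------------------------------------------------------
# Matching


@dataclass
class MatchResult:
    """All equal-size pairwise descriptor distances between two images."""

    pairs: list[tuple[int, int, float]]
    ms: float | None

    @property
    def valid(self) -> bool:
        return self.ms is not None

    @property
    def best(self) -> tuple[int, int, float] | None:
        if not self.pairs:
            return None
        return min(self.pairs, key=lambda p: p[2])

    def best_pairs(self, m: int) -> list[tuple[int, int, float]]:
        return sorted(self.pairs, key=lambda p: p[2])[:m]


def _distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(a - b))
    if metric == "cityblock":
        return float(np.sum(np.abs(a - b)))
    raise ValueError(f"unknown metric {metric!r}")


def match_structures(
    A: list[np.ndarray],
    B: list[np.ndarray],
    metric: str = "euclidean",
) -> MatchResult:
    """Pairwise similarity s_ij = d(v_i, v_j) over equal-size structures.

    Only structures with the same number of feature points (same
    descriptor dimension) are compared; ms is the minimum distance over
    all compared pairs, or None (invalid result) when no pair is
    comparable.
    """
    pairs: list[tuple[int, int, float]] = []
    for i, va in enumerate(A):
        for j, vb in enumerate(B):
            if va.shape == vb.shape:
                pairs.append((i, j, _distance(va, vb, metric)))
    ms = min((p[2] for p in pairs), default=None)
    return MatchResult(pairs=pairs, ms=ms)


def align_matched_pair(
    ca: CyclicStructure,
    cb: CyclicStructure,
    ga: SkeletonGraph,
    gb: SkeletonGraph,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-to-node correspondence between two matched structures.

    Both cycles are put in positive orientation; the cyclic offset of B
    minimizing the total squared difference of normalized edge-length
    profiles picks the node alignment.  Returns (points_a, points_b) of
    equal shape (n, 2).
    """
    if ca.n != cb.n:
        raise ValueError("structures must have the same size")

    def oriented(c: CyclicStructure, g: SkeletonGraph):
        nodes = list(c.node_ids)
        keys = list(c.edge_keys)
        if _polygon_area(c.positions) < 0:
            nodes = nodes[::-1]
            keys = (keys[-1:] + keys[:-1])[::-1]
        n = len(nodes)
        lens = np.array(
            [g.edge_length(nodes[i], nodes[(i + 1) % n], keys[i]) for i in range(n)]
        )
        pos = np.stack([g.pos(nid) for nid in nodes])
        return pos, lens / lens.sum()

    pa, la = oriented(ca, ga)
    pb, lb = oriented(cb, gb)
    n = ca.n
    offsets = [(float(np.sum((la - np.roll(lb, -s)) ** 2)), s) for s in range(n)]
    _, s = min(offsets)
    return pa, np.roll(pb, -s, axis=0)
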