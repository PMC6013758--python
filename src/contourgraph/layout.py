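"""Node-link layout for set-annotated graphs.

The pipeline realizes "preserve graph-theoretic distances, pull selected
set members together, and keep node glyphs from overlapping":

1. all-pairs shortest-path *target* distances over the network's
   unit-weight edges (:func:`graph_distances`);
2. for each selected group, a minimum spanning tree over its members
   weighted by those distances (:func:`spanning_graph`); the tree links,
   scaled by an attraction factor ``alpha < 1``, are injected as extra
   weighted links and the distances recomputed, which shortens the
   targets among set members;
3. stress majorization (SMACOF with a Guttman transform) from a seeded
   random initial placement minimizes
   ``sum_{u<v} w_uv (||p_u - p_v|| - d_uv)^2`` with ``w_uv = d_uv^-2``;
   each transform step provably never increases the stress;
4. iterative pairwise separation displaces node glyph rectangles until
   no two (padded) rectangles intersect (:func:`remove_overlaps`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .model import Group, LayoutResult, Network, SetSystem, SpanningGraph, canonical_edge

__all__ = [
    "DistanceMatrix",
    "LayoutParams",
    "graph_distances",
    "spanning_graph",
    "stress",
    "compute_layout",
    "remove_overlaps",
    "glyph_half_extents",
    "find_overlaps",
]

#: factor applied to the finite diameter to place disconnected pairs
DISCONNECTED_FACTOR = 1.5


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric target distances d(u, v) in hop units over all nodes.

    ``weights`` is the stress weighting ``d^-2`` (zero on the diagonal),
    which emphasizes short-range distance preservation.
    """

    nodes: tuple[str, ...]
    d: np.ndarray

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def distance(self, u: str, v: str) -> float:
        return float(self.d[self.index(u), self.index(v)])

    @property
    def weights(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            w = 1.0 / np.square(self.d)
        np.fill_diagonal(w, 0.0)
        return w


@dataclass
class LayoutParams:
    """Tunable layout parameters (abstract layout units).

    ``alpha`` scales spanning-tree links injected as shortcuts for
    selected sets (< 1 pulls members closer); ``edge_length`` converts
    hop-unit target distances to layout units; glyph metrics approximate
    a monospace label box: width = char_width * len(label) + char_pad,
    height = glyph_height.
    """

    alpha: float = 0.7
    edge_length: float = 80.0
    max_iter: int = 300
    tol: float = 1e-6
    padding: float = 2.0
    max_sweeps: int = 200
    char_width: float = 7.0
    char_pad: float = 10.0
    glyph_height: float = 18.0
    labels: Mapping[str, str] | None = None


def graph_distances(
    network: Network,
    extra_links: Iterable[tuple[str, str, float]] = (),
) -> DistanceMatrix:
    """All-pairs shortest paths over unit edges plus weighted extra links.

    Parallel links keep the smaller weight.  Disconnected pairs get a
    surrogate distance of 1.5x the finite diameter (1.5 when the graph
    has no finite off-diagonal distance at all), keeping components
    nearby but separate.
    """
    nodes = tuple(network.nodes)
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    adj = np.full((n, n), np.inf)
    for u, v in network.edges:
        i, j = idx[u], idx[v]
        adj[i, j] = adj[j, i] = min(adj[i, j], 1.0)
    for u, v, w in extra_links:
        if w <= 0:
            raise ValueError(f"extra link ({u!r}, {v!r}) has non-positive weight {w}")
        i, j = idx[u], idx[v]
        adj[i, j] = adj[j, i] = min(adj[i, j], float(w))
    adj[np.isinf(adj)] = 0.0  # csgraph convention: 0 = no edge (no zero-weight links here)
    d = shortest_path(adj, method="D", directed=False, unweighted=False)
    np.fill_diagonal(d, 0.0)
    finite_off = d[np.isfinite(d) & (d > 0)]
    surrogate = DISCONNECTED_FACTOR * (finite_off.max() if finite_off.size else 1.0)
    d[np.isinf(d)] = surrogate
    return DistanceMatrix(nodes=nodes, d=d)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def spanning_graph(
    network: Network, group: Group, base_distances: DistanceMatrix
) -> SpanningGraph:
    """Minimum spanning tree over a group's members.

    The complete graph on the members is weighted by the base
    graph-theoretic distances; Kruskal with a lexicographic (weight,
    endpoints) edge order makes the tree deterministic under ties.
    A singleton group yields zero links.
    """
    members = sorted(group.members)
    candidates = []
    for i, u in enumerate(members):
        for v in members[i + 1 :]:
            candidates.append((base_distances.distance(u, v), u, v))
    candidates.sort()
    uf = _UnionFind(members)
    links: list[tuple[str, str, float]] = []
    for w, u, v in candidates:
        if uf.union(u, v):
            links.append((u, v, w))
            if len(links) == len(members) - 1:
                break
    return SpanningGraph(group_id=group.id, vertices=tuple(members), links=tuple(links))


def stress(
    positions: Mapping[str, tuple[float, float]] | np.ndarray,
    distances: DistanceMatrix,
    scale: float = 1.0,
) -> float:
    """Weighted stress: sum over pairs of w * (realized - scale*target)^2."""
    if isinstance(positions, np.ndarray):
        x = np.asarray(positions, dtype=float)
    else:
        x = np.array([positions[n] for n in distances.nodes], dtype=float)
    d = distances.d * scale
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(d)
    np.fill_diagonal(w, 0.0)
    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    err = r - d
    np.fill_diagonal(err, 0.0)
    return float(np.sum(w * err * err) / 2.0)


def _majorize(
    x0: np.ndarray, d: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float]]:
    """SMACOF iteration via the Guttman transform; stress never increases."""
    n = len(d)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(d)
    np.fill_diagonal(w, 0.0)
    v = np.diag(w.sum(axis=1)) - w
    v_pinv = np.linalg.pinv(v)

    def _stress(x):
        diff = x[:, None, :] - x[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        err = r - d
        np.fill_diagonal(err, 0.0)
        return float(np.sum(w * err * err) / 2.0)

    x = x0 - x0.mean(axis=0)
    history = [_stress(x)]
    for _ in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r > 0, d / np.where(r > 0, r, 1.0), 0.0)
        b = -w * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = v_pinv @ (b @ x)
        s = _stress(x)
        history.append(s)
        prev = history[-2]
        if prev > 0 and (prev - s) / prev < tol:
            break
    return x, history


def restrict_group(group: Group, network: Network) -> Group | None:
    """Intersect a group's members with the drawn network's nodes.

    Returns None when no member is drawn (the group contributes neither
    attraction nor a contour).
    """
    present = group.members & network.node_set
    if not present:
        warnings.warn(f"group {group.id!r} has no member in the drawn network")
        return None
    if present == group.members:
        return group
    from dataclasses import replace

    return replace(group, members=frozenset(present))


def glyph_half_extents(
    nodes: Sequence[str],
    labels: Mapping[str, str] | None,
    params: LayoutParams,
) -> dict[str, tuple[float, float]]:
    """Monospace-approximated label-box half extents per node."""
    out = {}
    for n in nodes:
        label = (labels or {}).get(n, n)
        width = params.char_width * max(len(label), 1) + params.char_pad
        out[n] = (width / 2.0, params.glyph_height / 2.0)
    return out


def compute_layout(
    network: Network,
    set_system: SetSystem | None = None,
    seed: int = 0,
    params: LayoutParams | None = None,
) -> LayoutResult:
    """Full layout: distances -> set attraction -> majorization -> overlap removal.

    Selected groups contribute their spanning-tree links, scaled by
    ``params.alpha``, as extra weighted links before the target distances
    are recomputed; this pulls each selected set's members together.
    Reproducible: identical inputs and seed give identical positions.
    """
    params = params or LayoutParams()
    nodes = tuple(network.nodes)
    if not nodes:
        raise ValueError("cannot lay out an empty network")
    half = glyph_half_extents(nodes, params.labels, params)

    if len(nodes) == 1:
        return LayoutResult(
            positions={nodes[0]: (0.0, 0.0)},
            half_extents=half,
            seed=seed,
            stress_history=(),
            iterations=0,
        )

    base = graph_distances(network)
    extras: list[tuple[str, str, float]] = []
    if set_system is not None:
        for group in set_system.selected_groups():
            group = restrict_group(group, network)
            if group is None:
                continue
            tree = spanning_graph(network, group, base)
            extras.extend((u, v, params.alpha * w) for u, v, w in tree.links)
    targets = graph_distances(network, extras) if extras else base

    rng = np.random.default_rng(seed)
    n = len(nodes)
    x0 = rng.uniform(0.0, 1.0, size=(n, 2)) * math.sqrt(n)
    d_scaled = targets.d * params.edge_length
    x, history = _majorize(x0 * params.edge_length, d_scaled, params.max_iter, params.tol)

    layout = LayoutResult(
        positions={node: (float(p[0]), float(p[1])) for node, p in zip(nodes, x)},
        half_extents=half,
        seed=seed,
        stress_history=tuple(history),
        iterations=len(history) - 1,
    )
    return remove_overlaps(layout, padding=params.padding, max_sweeps=params.max_sweeps)


def find_overlaps(
    layout: LayoutResult, padding: float = 2.0
) -> list[tuple[str, str]]:
    """All pairs of node glyph rectangles that intersect once padded."""
    nodes = list(layout.positions)
    out = []
    for i, u in enumerate(nodes):
        xu, yu = layout.positions[u]
        hwu, hhu = layout.half_extents[u]
        for v in nodes[i + 1 :]:
            xv, yv = layout.positions[v]
            hwv, hhv = layout.half_extents[v]
            if abs(xu - xv) < hwu + hwv + padding and abs(yu - yv) < hhu + hhv + padding:
                out.append((u, v))
    return out


def remove_overlaps(
    layout: LayoutResult, padding: float = 2.0, max_sweeps: int = 200
) -> LayoutResult:
    """Separate intersecting glyph rectangles by pairwise displacement.

    Each sweep visits node pairs in input order and pushes every
    overlapping pair apart along the axis needing the smaller
    displacement (half the displacement each way); coincident centers
    are pushed apart along x.  When sweeps stall on a dense cluster
    (pairwise pushes can cycle), every 20th still-overlapping sweep
    additionally spreads all positions 5% outward from their centroid,
    which breaks the cycle deterministically.  Stops when a sweep moves
    nothing.  If the sweep budget is exhausted first, a warning is
    issued and ``overlap_converged`` is False on the (best-so-far)
    result.
    """
    nodes = list(layout.positions)
    pos = {n: list(layout.positions[n]) for n in nodes}
    converged = False
    for sweep in range(max_sweeps):
        if sweep > 0 and sweep % 20 == 0:
            cx = sum(p[0] for p in pos.values()) / len(pos)
            cy = sum(p[1] for p in pos.values()) / len(pos)
            for p in pos.values():
                p[0] = cx + (p[0] - cx) * 1.05
                p[1] = cy + (p[1] - cy) * 1.05
        moved = False
        for i, u in enumerate(nodes):
            hwu, hhu = layout.half_extents[u]
            for v in nodes[i + 1 :]:
                hwv, hhv = layout.half_extents[v]
                dx = pos[v][0] - pos[u][0]
                dy = pos[v][1] - pos[u][1]
                ox = (hwu + hwv + padding) - abs(dx)
                oy = (hhu + hhv + padding) - abs(dy)
                if ox <= 0 or oy <= 0:
                    continue
                moved = True
                if dx == 0 and dy == 0:
                    # coincident centers: tie-break along x
                    pos[u][0] -= ox / 2.0
                    pos[v][0] += ox / 2.0
                elif ox <= oy:
                    s = 1.0 if dx >= 0 else -1.0
                    pos[u][0] -= s * ox / 2.0
                    pos[v][0] += s * ox / 2.0
                else:
                    s = 1.0 if dy >= 0 else -1.0
                    pos[u][1] -= s * oy / 2.0
                    pos[v][1] += s * oy / 2.0
        if not moved:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"overlap removal did not converge within {max_sweeps} sweeps; "
            "returning best-so-far positions"
        )
    return LayoutResult(
        positions={n: (pos[n][0], pos[n][1]) for n in nodes},
        half_extents=dict(layout.half_extents),
        seed=layout.seed,
        stress_history=layout.stress_history,
        iterations=layout.iterations,
        overlap_converged=converged,
    )
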