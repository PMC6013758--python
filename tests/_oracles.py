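"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (triple loops, exhaustive
enumeration, ray casting) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math


def floyd_warshall(nodes, edges, extra_links=(), disconnected_factor=1.5):
    """All-pairs shortest paths by the textbook triple loop.

    Unit weights on *edges*, explicit weights on *extra_links*;
    disconnected pairs get ``disconnected_factor`` times the largest
    finite distance (1.0 if there is none), mirroring the layout
    contract.
    """
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    d = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for u, v in edges:
        i, j = idx[u], idx[v]
        d[i][j] = d[j][i] = min(d[i][j], 1.0)
    for u, v, w in extra_links:
        i, j = idx[u], idx[v]
        d[i][j] = d[j][i] = min(d[i][j], float(w))
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i][j])]
    surrogate = disconnected_factor * (max(finite) if finite else 1.0)
    for i in range(n):
        for j in range(n):
            if math.isinf(d[i][j]):
                d[i][j] = surrogate
    return {(u, v): d[idx[u]][idx[v]] for u in nodes for v in nodes}


def min_spanning_tree_weight(members, weight_of):
    """Minimum total weight over ALL spanning trees, by enumeration.

    ``weight_of(u, v)`` gives the edge weight.  Enumerates every
    (k-1)-subset of the complete graph's edges and keeps the cheapest
    acyclic connected one.  Only viable for small k.
    """
    members = list(members)
    k = len(members)
    if k <= 1:
        return 0.0
    all_edges = list(itertools.combinations(members, 2))
    best = math.inf
    for subset in itertools.combinations(all_edges, k - 1):
        parent = {m: m for m in members}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[rv] = ru
        if not acyclic:
            continue
        best = min(best, sum(weight_of(u, v) for u, v in subset))
    return best


def naive_stress(positions, targets, weights):
    """Double-loop weighted stress over explicit pair dictionaries."""
    nodes = list(positions)
    total = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            dx = positions[u][0] - positions[v][0]
            dy = positions[u][1] - positions[v][1]
            realized = math.hypot(dx, dy)
            total += weights[(u, v)] * (realized - targets[(u, v)]) ** 2
    return total


def point_in_ring(x, y, ring):
    """Ray-casting point-in-polygon test against one closed ring."""
    inside = False
    n = len(ring)
    for i in range(n - 1):  # ring is closed: last point repeats the first
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xcross > x:
                inside = not inside
    return inside


def point_in_boundary(x, y, rings):
    """Even-odd containment over a multi-ring boundary (holes supported)."""
    crossings = sum(point_in_ring(x, y, ring) for ring in rings)
    return crossings % 2 == 1


def overlapping_rectangle_pairs(positions, half_extents, padding):
    """Exhaustive O(n^2) padded rectangle-intersection scan."""
    nodes = list(positions)
    bad = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            dx = abs(positions[u][0] - positions[v][0])
            dy = abs(positions[u][1] - positions[v][1])
            if (
                dx < half_extents[u][0] + half_extents[v][0] + padding
                and dy < half_extents[u][1] + half_extents[v][1] + padding
            ):
                bad.append((u, v))
    return bad


def connected(members, edges):
    """BFS connectivity of *members* within the given edge set."""
    members = set(members)
    if len(members) <= 1:
        return True
    adj = {m: set() for m in members}
    for u, v in edges:
        if u in members and v in members:
            adj[u].add(v)
            adj[v].add(u)
    start = next(iter(members))
    seen = {start}
    queue = [start]
    while queue:
        node = queue.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen == members
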