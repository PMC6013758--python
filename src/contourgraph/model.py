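"""Core domain types for set-annotated graph visualization.

A *set-annotated graph* is a small undirected graph together with a
collection of possibly overlapping node sets ("groups"), e.g. enriched
GO terms / KEGG pathways over a subnetwork module, or communities in a
social network.  These types are shared by every pipeline stage: file
readers produce :class:`Network` and :class:`NodeTable`, the group stage
produces a :class:`SetSystem`, the layout stage a :class:`LayoutResult`
plus per-group :class:`SpanningGraph`, and the contour stage a
:class:`ContourShape` per selected group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Network",
    "ColumnType",
    "Column",
    "NodeTable",
    "Group",
    "SetSystem",
    "Settings",
    "LayoutResult",
    "SpanningGraph",
    "ContourShape",
    "validate_network",
    "canonical_edge",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """Undirected graph of identified nodes.

    Node ids are opaque, case-sensitive strings.  Edges are stored in
    canonical (lexicographically sorted) endpoint order and deduplicated;
    self-loops are not representable through :meth:`from_edges`.
    """

    nodes: tuple[str, ...] = ()
    edges: tuple[tuple[str, str], ...] = ()
    name: str = ""

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        name: str = "",
    ) -> "Network":
        """Build a normalized network from (possibly directed/duplicated) pairs.

        Nodes are collected in order of first appearance; reversed and
        duplicate edges collapse onto one stored edge; self-loops are
        dropped with a warning (the model is strictly simple/undirected).
        """
        nodes: dict[str, None] = {}
        edges: dict[tuple[str, str], None] = {}
        n_loops = 0
        for u, v in pairs:
            nodes.setdefault(u)
            nodes.setdefault(v)
            if u == v:
                n_loops += 1
                continue
            edges.setdefault(canonical_edge(u, v))
        for n in extra_nodes:
            nodes.setdefault(n)
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop edge(s)", stacklevel=2)
        return cls(nodes=tuple(nodes), edges=tuple(edges), name=name)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_edge(u, v) in set(self.edges)

    def degree(self, u: str) -> int:
        return sum(1 for a, b in self.edges if u in (a, b))

    def neighbors(self, u: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def validate_network(network: Network) -> list[str]:
    """Report every violated :class:`Network` invariant.

    Returns an empty list iff the network is well formed; each entry
    names the offending node or edge.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for n in network.nodes:
        if n in seen:
            violations.append(f"duplicate node id: {n!r}")
        seen.add(n)
    edge_seen: set[tuple[str, str]] = set()
    for u, v in network.edges:
        if u == v:
            violations.append(f"self-loop edge: ({u!r}, {v!r})")
            continue
        for endpoint in (u, v):
            if endpoint not in seen:
                violations.append(
                    f"edge ({u!r}, {v!r}) has endpoint {endpoint!r} not in nodes"
                )
        ce = canonical_edge(u, v)
        if ce in edge_seen:
            violations.append(f"duplicate edge: ({u!r}, {v!r})")
        edge_seen.add(ce)
    return violations


class ColumnType(Enum):
    """Annotation column types, 1:1 with the table dialect tokens."""

    STRING = "s"
    FLOAT = "f"
    STRING_LIST = "sl"

    @classmethod
    def from_token(cls, token: str) -> "ColumnType":
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown column type token {token!r}") from None


@dataclass
class Column:
    """One typed annotation column: cell values keyed by row key.

    Cell values are ``str`` for STRING, ``float | None`` for FLOAT
    (None = missing), and ``list[str]`` for STRING_LIST.
    """

    ctype: ColumnType
    values: dict[str, object] = field(default_factory=dict)


@dataclass
class NodeTable:
    """Typed per-node annotation table keyed to node ids.

    ``key`` names the key column; ``row_keys`` preserves file row order;
    ``columns`` maps column name -> :class:`Column` (insertion ordered).
    """

    key: str = "name"
    row_keys: tuple[str, ...] = ()
    columns: dict[str, Column] = field(default_factory=dict)

    def column_names(self) -> list[str]:
        return list(self.columns)

    def has_column(self, name: str) -> bool:
        return name in self.columns

    def column_type(self, name: str) -> ColumnType:
        return self.columns[name].ctype

    def cell(self, row_key: str, column: str):
        return self.columns[column].values.get(row_key)

    def unmatched_keys(self, network: Network) -> list[str]:
        """Row keys that match no node id of *network*."""
        ids = network.node_set
        return [k for k in self.row_keys if k not in ids]

    def merge(self, other: "NodeTable") -> "NodeTable":
        """Overlay *other* onto this table (later imports win per cell)."""
        keys = dict.fromkeys(self.row_keys)
        for k in other.row_keys:
            keys.setdefault(k)
        columns: dict[str, Column] = {
            name: Column(col.ctype, dict(col.values)) for name, col in self.columns.items()
        }
        for name, col in other.columns.items():
            if name in columns and columns[name].ctype == col.ctype:
                columns[name].values.update(col.values)
            else:
                columns[name] = Column(col.ctype, dict(col.values))
        return NodeTable(key=self.key, row_keys=tuple(keys), columns=columns)


@dataclass(frozen=True)
class Group:
    """A named node set with optional display annotation.

    ``score`` is a unitless enrichment score supplied by an upstream
    enrichment analysis; this package only displays it.
    """

    id: str
    source_column: str
    members: frozenset[str]
    label: Optional[str] = None
    url: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.id!r} has no members")

    @property
    def display_label(self) -> str:
        return self.label if self.label is not None else self.id


@dataclass
class SetSystem:
    """Ordered collection of groups plus the current selection.

    Selection order matters: it drives color assignment and contour
    z-order, so it is preserved exactly as given.
    """

    groups: list[Group] = field(default_factory=list)
    selection: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [g.id for g in self.groups]
        if len(ids) != len(set(ids)):
            raise ValueError("group ids must be unique within a SetSystem")
        unknown = [s for s in self.selection if s not in set(ids)]
        if unknown:
            raise ValueError(f"selection references unknown group ids: {unknown}")

    def group_ids(self) -> list[str]:
        return [g.id for g in self.groups]

    def by_id(self, gid: str) -> Group:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def selected_groups(self) -> list[Group]:
        return [self.by_id(gid) for gid in self.selection]


@dataclass
class Settings:
    """Visualization settings (column bindings and flags)."""

    label_column: Optional[str] = None
    url_column: Optional[str] = None
    score_column: Optional[str] = None
    show_score: bool = False
    selected_group_columns: tuple[str, ...] = ()


@dataclass
class LayoutResult:
    """2-D node positions and glyph half-extents, in abstract layout units."""

    positions: dict[str, tuple[float, float]]
    half_extents: dict[str, tuple[float, float]]
    seed: int = 0
    stress_history: tuple[float, ...] = ()
    iterations: int = 0
    overlap_converged: bool = True

    def validate(self) -> list[str]:
        bad = []
        for n, (x, y) in self.positions.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                bad.append(f"non-finite position for {n!r}")
        for n, (hw, hh) in self.half_extents.items():
            if not (hw > 0 and hh > 0):
                bad.append(f"non-positive glyph half-extent for {n!r}")
        return bad

    def circumradius(self, node: str) -> float:
        """Radius of the circle circumscribing the node's glyph rectangle."""
        hw, hh = self.half_extents[node]
        return math.hypot(hw, hh)


@dataclass(frozen=True)
class SpanningGraph:
    """Tree connecting a group's members, weighted by graph distance (hops).

    Used twice: its links are injected (scaled) into the layout's target
    distances to pull members together, and its skeleton is inflated into
    the group's rounded contour.
    """

    group_id: str
    vertices: tuple[str, ...]
    links: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        if len(self.links) != max(len(self.vertices) - 1, 0):
            raise ValueError(
                f"spanning graph of {self.group_id!r} is not a tree: "
                f"{len(self.vertices)} vertices, {len(self.links)} links"
            )


@dataclass
class ContourShape:
    """Closed rounded region(s) for one selected group.

    ``boundary`` holds one or more closed polylines (first point equals
    last point) in layout units; colors are attached by the scene builder.
    """

    group_id: str
    boundary: list  # list of (k, 2) float arrays, closed rings
    fill: str = "#cccccc"
    fill_opacity: float = 0.25
    outline: str = "#888888"
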