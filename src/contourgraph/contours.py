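"""Rounded set contours and drawing-order scene assembly.

Each selected group's contour is the outline of the union of discs
around its member glyphs and rounded "sausages" along its spanning-tree
links — the tree skeleton inflated into a closed rounded region that
visually encompasses and connects the members.  Overlapping contours are
alpha-blended; the scene painter draws larger sets first (below) so
small sets remain visible on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .groups import format_score
from .model import (
    ContourShape,
    LayoutResult,
    Network,
    SetSystem,
    Settings,
    SpanningGraph,
)

__all__ = [
    "ContourError",
    "PALETTE",
    "contour_shape",
    "build_scene",
    "Scene",
    "ContourLayer",
    "NodeGlyph",
]


class ContourError(ValueError):
    """Degenerate contour geometry."""


#: 12 distinct qualitative hues; assigned to groups by selection order.
PALETTE = (
    "#1f77b4",
    "#ff7f0e",
    "#2ca02c",
    "#d62728",
    "#9467bd",
    "#8c564b",
    "#e377c2",
    "#bcbd22",
    "#17becf",
    "#aec7e8",
    "#ffbb78",
    "#98df8a",
)

#: default contour inflation radius, layout units
DEFAULT_RADIUS = 14.0

#: polygonal approximation: quarter-circle segments (>= 4 => >= 16 per circle)
QUAD_SEGS = 16


def contour_shape(
    spanning: SpanningGraph,
    layout: LayoutResult,
    radius: float = DEFAULT_RADIUS,
    quad_segs: int = QUAD_SEGS,
) -> ContourShape:
    """Union of member discs and link sausages, as closed polylines.

    Each member contributes a disc of radius ``radius`` plus the glyph's
    circumradius (so the glyph rectangle fits inside); each spanning
    link contributes a rounded-end band of half-width ``radius`` along
    the segment between its endpoints.  For a tree skeleton the union
    has exactly one connected component; its exterior ring (plus any
    interior rings) is returned, approximated with at least 16 segments
    per full circle.
    """
    if radius <= 0:
        raise ContourError(f"contour radius must be positive, got {radius}")
    if quad_segs < 4:
        raise ContourError("need at least 4 segments per quarter circle")
    pieces = []
    for member in spanning.vertices:
        x, y = layout.positions[member]
        pieces.append(Point(x, y).buffer(radius + layout.circumradius(member), quad_segs=quad_segs))
    for u, v, _w in spanning.links:
        pieces.append(
            LineString([layout.positions[u], layout.positions[v]]).buffer(
                radius, quad_segs=quad_segs
            )
        )
    merged = unary_union(pieces)
    if merged.is_empty or merged.area <= 0:
        raise ContourError(f"group {spanning.group_id!r}: degenerate contour geometry")
    polygons = list(merged.geoms) if isinstance(merged, MultiPolygon) else [merged]
    rings: list[np.ndarray] = []
    for poly in polygons:
        rings.append(np.asarray(poly.exterior.coords, dtype=float))
        for interior in poly.interiors:
            rings.append(np.asarray(interior.coords, dtype=float))
    return ContourShape(group_id=spanning.group_id, boundary=rings)


@dataclass
class NodeGlyph:
    node_id: str
    x: float
    y: float
    hw: float
    hh: float
    label: str
    url: Optional[str] = None


@dataclass
class ContourLayer:
    shape: ContourShape
    label: str
    label_xy: Optional[tuple[float, float]] = None
    score_text: Optional[str] = None
    member_count: int = 0


@dataclass
class Scene:
    """Ordered drawing list handed to the SVG writer.

    ``contours`` is already in painting order: largest member count
    first, so smaller sets paint above larger ones; edges, then node
    glyphs with labels, paint above all contours.
    """

    contours: list[ContourLayer] = field(default_factory=list)
    edges: list[tuple[float, float, float, float]] = field(default_factory=list)
    nodes: list[NodeGlyph] = field(default_factory=list)


def _node_label(node: str, table, settings: Settings) -> str:
    col = settings.label_column
    if col is None:
        return node
    if table is None or not table.has_column(col):
        return node
    value = table.cell(node, col)
    return str(value) if value not in (None, "") else node


def _node_url(node: str, table, settings: Settings) -> Optional[str]:
    col = settings.url_column
    if col is None or table is None or not table.has_column(col):
        return None
    value = table.cell(node, col)
    return str(value) if value not in (None, "") else None


def _label_anchor(shape: ContourShape, centroid: np.ndarray) -> tuple[float, float]:
    """Boundary point farthest from the graph centroid (label placement)."""
    best, best_d = None, -1.0
    for ring in shape.boundary:
        deltas = ring - centroid[None, :]
        dist = np.hypot(deltas[:, 0], deltas[:, 1])
        k = int(np.argmax(dist))
        if dist[k] > best_d:
            best_d = float(dist[k])
            best = (float(ring[k, 0]), float(ring[k, 1]))
    return best


def build_scene(
    network: Network,
    set_system: SetSystem,
    layout: LayoutResult,
    settings: Settings | None = None,
    node_table=None,
    radius: float = DEFAULT_RADIUS,
) -> Scene:
    """Assemble the full drawing list for a laid-out annotated network.

    Contours are built from each selected group's spanning tree (over
    unit-edge graph distances), colored from the palette by selection
    order, and z-ordered by decreasing member count.  Node labels come
    from the settings' label column, falling back to the node id with a
    warning when the column is missing.
    """
    from .layout import graph_distances, restrict_group, spanning_graph  # avoids cycle

    settings = settings or Settings()
    if settings.label_column and (
        node_table is None or not node_table.has_column(settings.label_column)
    ):
        warnings.warn(
            f"label column {settings.label_column!r} not found; using node ids"
        )

    centroid = np.array(
        [
            np.mean([layout.positions[n][0] for n in network.nodes]),
            np.mean([layout.positions[n][1] for n in network.nodes]),
        ]
    )

    layers: list[ContourLayer] = []
    if set_system.selection:
        base = graph_distances(network)
        for order, gid in enumerate(set_system.selection):
            group = restrict_group(set_system.by_id(gid), network)
            if group is None:
                continue
            tree = spanning_graph(network, group, base)
            shape = contour_shape(tree, layout, radius=radius)
            color = PALETTE[order % len(PALETTE)]
            shape.fill = color
            shape.outline = color
            score_text = None
            if settings.show_score and group.score is not None:
                score_text = format_score(group.score)
            layers.append(
                ContourLayer(
                    shape=shape,
                    label=group.display_label,
                    label_xy=_label_anchor(shape, centroid),
                    score_text=score_text,
                    member_count=len(group.members),
                )
            )
        # paint large sets first so small sets stay visible on top;
        # stable sort keeps selection order among equal sizes
        layers.sort(key=lambda la: -la.member_count)

    edges = [
        (
            layout.positions[u][0],
            layout.positions[u][1],
            layout.positions[v][0],
            layout.positions[v][1],
        )
        for u, v in network.edges
    ]
    glyphs = [
        NodeGlyph(
            node_id=n,
            x=layout.positions[n][0],
            y=layout.positions[n][1],
            hw=layout.half_extents[n][0],
            hh=layout.half_extents[n][1],
            label=_node_label(n, node_table, settings),
            url=_node_url(n, node_table, settings),
        )
        for n in network.nodes
    ]
    return Scene(contours=layers, edges=edges, nodes=glyphs)
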