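"""Readers and writers for the tool's file dialects.

Supported inputs:

* tab-separated edge lists with configurable 1-based id columns,
* SIF (``node <tab> relation <tab> node``) as a convenience,
* GML networks (via :mod:`networkx`),
* tab-separated typed annotation tables whose column types are given by
  a comma-separated token string (``s`` string, ``f`` float, ``sl``
  pipe-separated string list).

Output is SVG 1.1 written from a :class:`~contourgraph.contours.Scene`.
Column indices at this boundary are 1-based, matching the command
arguments published for these workflows; internal storage is 0-based and
the conversion happens exactly once, here.
"""

from __future__ import annotations

import csv
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Sequence

from .model import Column, ColumnType, Network, NodeTable

__all__ = [
    "DialectError",
    "parse_type_spec",
    "split_list_cell",
    "read_edge_list",
    "read_sif",
    "read_gml",
    "read_node_table",
    "read_table_rows",
    "infer_type_spec",
    "write_edge_list",
    "write_node_table",
    "write_svg",
]

SVG_NS = "http://www.w3.org/2000/svg"


class DialectError(ValueError):
    """Malformed input in one of the supported text dialects."""


def parse_type_spec(spec: str) -> tuple[ColumnType, ...]:
    """Parse a comma-separated column-type token string.

    ``"s,s,f,sl"`` -> (STRING, STRING, FLOAT, STRING_LIST).  Unknown
    tokens raise :class:`DialectError` naming the token and its 1-based
    position.
    """
    if not spec or not spec.strip():
        raise DialectError("empty column type specification")
    out = []
    for pos, token in enumerate(spec.split(","), start=1):
        token = token.strip()
        try:
            out.append(ColumnType.from_token(token))
        except ValueError:
            raise DialectError(
                f"unknown column type token {token!r} at position {pos}"
            ) from None
    return tuple(out)


def split_list_cell(cell: str) -> list[str]:
    """Split a pipe-separated list cell, dropping empty/whitespace tokens."""
    if cell is None:
        return []
    return [tok.strip() for tok in cell.split("|") if tok.strip()]


def _read_rows(path) -> list[list[str]]:
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        return [row for row in reader]


def read_edge_list(
    path,
    source_column: int = 1,
    target_column: int = 2,
    name: str | None = None,
) -> Network:
    """Read a tab-separated edge list; id columns are 1-based.

    Blank lines and ``#`` comment lines are skipped.  Duplicate and
    reversed pairs collapse onto a single stored edge.  If the two column
    indices coincide (as in some published command calls) the reader
    warns and uses columns ``(k, k+1)``.
    """
    if source_column < 1 or target_column < 1:
        raise ValueError("column indices are 1-based and must be >= 1")
    if source_column == target_column:
        warnings.warn(
            f"source and target column are both {source_column}; "
            f"using columns ({source_column}, {source_column + 1})",
            stacklevel=2,
        )
        target_column = source_column + 1
    need = max(source_column, target_column)
    pairs: list[tuple[str, str]] = []
    for lineno, row in enumerate(_read_rows(path), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].lstrip().startswith("#"):
            continue
        if len(row) < need:
            raise DialectError(
                f"{path}: line {lineno}: expected at least {need} columns, got {len(row)}"
            )
        pairs.append((row[source_column - 1].strip(), row[target_column - 1].strip()))
    return Network.from_edges(pairs, name=name or Path(path).stem)


def read_sif(path, name: str | None = None) -> Network:
    """Read a simple-interaction-format file (source, relation, target)."""
    return read_edge_list(path, source_column=1, target_column=3, name=name)


def read_gml(path, name: str | None = None) -> Network:
    """Read a GML network.

    Node id = GML ``label`` when present, else the stringified GML id.
    Directed GML graphs are symmetrized with a warning.
    """
    import networkx as nx

    try:
        g = nx.read_gml(path, label=None)
    except Exception as exc:  # networkx raises several parser error types
        if "duplicated" in str(exc):
            # duplicate edge records are legal input here and collapse to
            # one edge: re-parse as a multigraph, then simplify
            text = Path(path).read_text(encoding="utf-8")
            text = text.replace("graph [", "graph [\n  multigraph 1", 1)
            try:
                g = nx.parse_gml(text, label=None)
            except Exception as exc2:
                raise DialectError(f"{path}: malformed GML: {exc2}") from exc2
        else:
            raise DialectError(f"{path}: malformed GML: {exc}") from exc
    if g.is_directed():
        warnings.warn(f"{path}: directed GML symmetrized to an undirected network")
        g = g.to_undirected()
    names: dict[object, str] = {}
    for nid, data in g.nodes(data=True):
        label = data.get("label")
        names[nid] = str(label) if label not in (None, "") else str(nid)
    if len(set(names.values())) != len(names):
        raise DialectError(f"{path}: GML node labels/ids are not unique")
    pairs = [(names[u], names[v]) for u, v in g.edges()]
    return Network.from_edges(pairs, extra_nodes=names.values(), name=name or Path(path).stem)


def _parse_cell(raw: str, ctype: ColumnType, where: str):
    if ctype is ColumnType.STRING:
        return raw.strip()
    if ctype is ColumnType.STRING_LIST:
        return split_list_cell(raw)
    # FLOAT: empty or unparsable -> missing (None), with a warning for garbage
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        warnings.warn(f"{where}: cannot parse {raw!r} as float; treating as missing")
        return None
    if value != value or value in (float("inf"), float("-inf")):
        warnings.warn(f"{where}: non-finite float {raw!r}; treating as missing")
        return None
    return value


def read_node_table(
    path,
    key_column: int = 1,
    type_spec: Sequence[ColumnType] | None = None,
    first_row_names: bool = True,
    start_row: int = 1,
) -> NodeTable:
    """Read a tab-separated typed annotation table.

    ``key_column`` and ``start_row`` are 1-based; ``start_row`` counts
    data rows after the optional header.  When ``type_spec`` is omitted
    the types are inferred (float iff every non-empty cell parses as a
    float, else string; lists are never inferred).
    """
    rows = [r for r in _read_rows(path) if r and any(c.strip() for c in r)]
    if not rows:
        return NodeTable()
    header: list[str] | None = None
    if first_row_names:
        header, rows = rows[0], rows[1:]
    rows = rows[start_row - 1 :]
    width = len(header) if header is not None else (len(rows[0]) if rows else 0)
    if type_spec is None:
        type_spec = infer_type_spec(rows, width)
    if len(type_spec) != width:
        raise DialectError(
            f"{path}: type spec has {len(type_spec)} tokens but table has {width} columns"
        )
    if not 1 <= key_column <= width:
        raise DialectError(f"{path}: key column {key_column} out of range 1..{width}")
    if header is None:
        header = [f"col{i}" for i in range(1, width + 1)]
    header = [h.strip() for h in header]

    key_name = header[key_column - 1]
    row_keys: list[str] = []
    columns = {
        name: Column(ctype)
        for name, ctype in zip(header, type_spec)
        if name != key_name
    }
    offset = (2 if first_row_names else 1) + (start_row - 1)
    for i, row in enumerate(rows):
        lineno = i + offset
        if len(row) != width:
            raise DialectError(
                f"{path}: line {lineno}: expected {width} columns, got {len(row)}"
            )
        key = row[key_column - 1].strip()
        if not key:
            raise DialectError(f"{path}: line {lineno}: empty key cell")
        row_keys.append(key)
        for j, (name, ctype) in enumerate(zip(header, type_spec)):
            if name == key_name:
                continue
            columns[name].values[key] = _parse_cell(
                row[j], ctype, f"{path}: line {lineno}, column {name!r}"
            )
    return NodeTable(key=key_name, row_keys=tuple(row_keys), columns=columns)


def read_table_rows(path) -> list[list[str]]:
    """Raw tab-separated rows (used by callers that route rows themselves)."""
    return _read_rows(path)


def infer_type_spec(rows: list[list[str]], width: int) -> tuple[ColumnType, ...]:
    """Infer s/f column types from data rows (never infers list columns)."""
    types = []
    for j in range(width):
        cells = [r[j].strip() for r in rows if j < len(r) and r[j].strip()]
        is_float = bool(cells)
        for c in cells:
            try:
                float(c)
            except ValueError:
                is_float = False
                break
        types.append(ColumnType.FLOAT if is_float else ColumnType.STRING)
    return tuple(types)


def write_edge_list(network: Network, path, relation: str = "pp") -> None:
    """Write a 3-column (relation, source, target) tab-separated edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in network.edges:
            fh.write(f"{relation}\t{u}\t{v}\n")


def _format_cell(value, ctype: ColumnType) -> str:
    if value is None:
        return ""
    if ctype is ColumnType.STRING_LIST:
        return "|".join(value)
    if ctype is ColumnType.FLOAT:
        return repr(float(value))
    return str(value)


def write_node_table(table: NodeTable, path) -> None:
    """Write a NodeTable back to the tab-separated typed dialect."""
    names = table.column_names()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([table.key] + names) + "\n")
        for key in table.row_keys:
            cells = [key] + [
                _format_cell(table.columns[n].values.get(key), table.columns[n].ctype)
                for n in names
            ]
            fh.write("\t".join(cells) + "\n")


def type_spec_of(table: NodeTable) -> str:
    """Token string (key column first) describing a NodeTable's dialect."""
    tokens = ["s"] + [table.columns[n].ctype.value for n in table.column_names()]
    return ",".join(tokens)


# ---------------------------------------------------------------------------
# SVG writing


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def write_svg(scene, path) -> None:
    """Write a scene as SVG 1.1.

    Painting order (background to foreground): set contours, edges, node
    glyphs, node labels, group labels/score badges.  Layout coordinates
    are mapped into a viewBox with a 5% margin; SVG's y axis grows
    downward and layout coordinates are used as-is (they are abstract).
    """
    xs: list[float] = []
    ys: list[float] = []
    for glyph in scene.nodes:
        xs += [glyph.x - glyph.hw, glyph.x + glyph.hw]
        ys += [glyph.y - glyph.hh, glyph.y + glyph.hh]
    for layer in scene.contours:
        for ring in layer.shape.boundary:
            xs += [float(p[0]) for p in ring]
            ys += [float(p[1]) for p in ring]
    if not xs:
        xs, ys = [0.0, 1.0], [0.0, 1.0]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    mx = 0.05 * max(x1 - x0, 1.0)
    my = 0.05 * max(y1 - y0, 1.0)
    viewbox = (x0 - mx, y0 - my, (x1 - x0) + 2 * mx, (y1 - y0) + 2 * my)

    ET.register_namespace("", SVG_NS)
    root = ET.Element(
        f"{{{SVG_NS}}}svg",
        {
            "version": "1.1",
            "viewBox": " ".join(_fmt(v) for v in viewbox),
            "width": _fmt(viewbox[2]),
            "height": _fmt(viewbox[3]),
        },
    )

    contours_g = ET.SubElement(root, f"{{{SVG_NS}}}g", {"class": "contours"})
    for layer in scene.contours:
        d_parts = []
        for ring in layer.shape.boundary:
            d_parts.append(
                "M "
                + " L ".join(f"{_fmt(float(p[0]))},{_fmt(float(p[1]))}" for p in ring[:-1])
                + " Z"
            )
        ET.SubElement(
            contours_g,
            f"{{{SVG_NS}}}path",
            {
                "class": "contour",
                "d": " ".join(d_parts),
                "fill": layer.shape.fill,
                "fill-opacity": _fmt(layer.shape.fill_opacity),
                "stroke": layer.shape.outline,
                "stroke-width": "1.5",
                "fill-rule": "evenodd",
                "data-group": layer.shape.group_id,
            },
        )

    edges_g = ET.SubElement(root, f"{{{SVG_NS}}}g", {"class": "edges"})
    for x1e, y1e, x2e, y2e in scene.edges:
        ET.SubElement(
            edges_g,
            f"{{{SVG_NS}}}line",
            {
                "x1": _fmt(x1e),
                "y1": _fmt(y1e),
                "x2": _fmt(x2e),
                "y2": _fmt(y2e),
                "stroke": "#555555",
                "stroke-width": "1",
            },
        )

    nodes_g = ET.SubElement(root, f"{{{SVG_NS}}}g", {"class": "nodes"})
    for glyph in scene.nodes:
        group = ET.SubElement(nodes_g, f"{{{SVG_NS}}}g", {"data-node": glyph.node_id})
        parent = group
        if glyph.url:
            parent = ET.SubElement(group, f"{{{SVG_NS}}}a", {"href": glyph.url})
        ET.SubElement(
            parent,
            f"{{{SVG_NS}}}rect",
            {
                "x": _fmt(glyph.x - glyph.hw),
                "y": _fmt(glyph.y - glyph.hh),
                "width": _fmt(2 * glyph.hw),
                "height": _fmt(2 * glyph.hh),
                "rx": _fmt(min(glyph.hw, glyph.hh) * 0.6),
                "fill": "#ffffff",
                "stroke": "#333333",
            },
        )
        text = ET.SubElement(
            parent,
            f"{{{SVG_NS}}}text",
            {
                "x": _fmt(glyph.x),
                "y": _fmt(glyph.y),
                "text-anchor": "middle",
                "dominant-baseline": "central",
                "font-family": "monospace",
                "font-size": "12",
            },
        )
        text.text = glyph.label

    labels_g = ET.SubElement(root, f"{{{SVG_NS}}}g", {"class": "group-labels"})
    for layer in scene.contours:
        if layer.label_xy is None:
            continue
        text = ET.SubElement(
            labels_g,
            f"{{{SVG_NS}}}text",
            {
                "x": _fmt(layer.label_xy[0]),
                "y": _fmt(layer.label_xy[1]),
                "text-anchor": "middle",
                "font-family": "sans-serif",
                "font-size": "13",
                "fill": layer.shape.outline,
                "class": "group-label",
            },
        )
        text.text = layer.label
        if layer.score_text is not None:
            badge = ET.SubElement(
                labels_g,
                f"{{{SVG_NS}}}text",
                {
                    "x": _fmt(layer.label_xy[0]),
                    "y": _fmt(layer.label_xy[1] + 14.0),
                    "text-anchor": "middle",
                    "font-family": "sans-serif",
                    "font-size": "11",
                    "fill": layer.shape.outline,
                    "class": "group-score",
                },
            )
            badge.text = layer.score_text

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("\n")
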