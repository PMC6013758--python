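"""Generate, annotate, select and remove overlapping node groups.

Groups are materialized from string-list annotation columns: every
distinct token appearing in a named column (within the chosen node
scope) becomes one group whose members are the scoped nodes carrying
that token.  This mirrors the generate/select/remove-groups command
semantics of set-oriented network visualization workflows.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Sequence

from .model import ColumnType, Group, Network, NodeTable, SetSystem

__all__ = [
    "GroupError",
    "generate_groups",
    "annotate_groups",
    "select_groups",
    "remove_groups",
]


class GroupError(ValueError):
    """Invalid group operation (missing column, bad type, empty scope...)."""


def generate_groups(
    network: Network,
    table: NodeTable,
    group_columns: Sequence[str],
    use_all_nodes: bool = True,
    selected_nodes: Iterable[str] = (),
) -> SetSystem:
    """Create one group per distinct token in the named list columns.

    Scope is either all network nodes (``use_all_nodes``) or the given
    selection.  Groups are ordered by (column order, first appearance of
    the token while scanning nodes in network order); members are the
    scoped nodes whose cell contains the token.  Tokens occurring in two
    different columns keep their bare token id unless that would collide,
    in which case the later group's id is qualified as
    ``"column:token"``.
    """
    for col in group_columns:
        if not table.has_column(col):
            raise GroupError(f"no such column: {col!r}")
        if table.column_type(col) is not ColumnType.STRING_LIST:
            raise GroupError(
                f"column {col!r} has type {table.column_type(col).value!r}, "
                "expected a string-list (sl) column"
            )
    if use_all_nodes:
        scope = list(network.nodes)
    else:
        node_ids = network.node_set
        scope = [n for n in selected_nodes if n in node_ids]
        if not scope:
            raise GroupError("empty node scope: nothing selected")

    groups: list[Group] = []
    seen_ids: set[str] = set()
    for col in group_columns:
        column = table.columns[col]
        members: dict[str, list[str]] = {}  # token -> members, insertion ordered
        for node in scope:
            for token in column.values.get(node) or ():
                members.setdefault(token, []).append(node)
        for token, nodes in members.items():
            gid = token
            if gid in seen_ids:
                gid = f"{col}:{token}"
                warnings.warn(
                    f"group token {token!r} occurs in more than one column; "
                    f"qualified as {gid!r}"
                )
            seen_ids.add(gid)
            groups.append(Group(id=gid, source_column=col, members=frozenset(nodes)))
    return SetSystem(groups=groups, selection=[])


def _first_present(table: NodeTable, preferred: str | None, fallbacks: Sequence[str]):
    """Resolve an annotation column name, case-insensitively for fallbacks."""
    if preferred and table.has_column(preferred):
        return preferred
    lower = {name.lower(): name for name in table.column_names()}
    for cand in ([preferred] if preferred else []) + list(fallbacks):
        if cand and cand.lower() in lower:
            return lower[cand.lower()]
    return None


def annotate_groups(
    set_system: SetSystem,
    group_table: NodeTable,
    label_column: str | None = None,
    url_column: str | None = None,
    score_column: str | None = None,
) -> SetSystem:
    """Fill label/url/score of groups from a table keyed by group id.

    Column bindings default to columns named ``Label``/``URL``/``Score``
    (case-insensitive).  Table keys that match no group id are warned
    about; groups without a matching row keep their defaults (label =
    id).
    """
    label_col = _first_present(group_table, label_column, ["Label", "Name", "Symbol"])
    url_col = _first_present(group_table, url_column, ["URL"])
    score_col = _first_present(group_table, score_column, ["Score"])

    known = {g.id for g in set_system.groups}
    unmatched = [k for k in group_table.row_keys if k not in known]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} group-annotation key(s) match no group: "
            + ", ".join(map(repr, unmatched[:5]))
            + ("..." if len(unmatched) > 5 else "")
        )

    keys = set(group_table.row_keys)
    new_groups = []
    for g in set_system.groups:
        if g.id not in keys:
            new_groups.append(g)
            continue
        changes = {}
        if label_col is not None:
            val = group_table.cell(g.id, label_col)
            if val not in (None, ""):
                changes["label"] = str(val)
        if url_col is not None:
            val = group_table.cell(g.id, url_col)
            if val not in (None, ""):
                changes["url"] = str(val)
        if score_col is not None:
            val = group_table.cell(g.id, score_col)
            if val is not None and val != "":
                try:
                    changes["score"] = float(val)
                except (TypeError, ValueError):
                    warnings.warn(f"group {g.id!r}: non-numeric score {val!r} ignored")
        new_groups.append(replace(g, **changes) if changes else g)
    return SetSystem(groups=new_groups, selection=list(set_system.selection))


def select_groups(set_system: SetSystem, ids: Sequence[str]) -> SetSystem:
    """Replace the selection by *ids* (order preserved).

    Unknown ids raise :class:`GroupError` listing all of them.
    """
    known = set(g.id for g in set_system.groups)
    unknown = [gid for gid in ids if gid not in known]
    if unknown:
        raise GroupError(f"unknown group id(s): {', '.join(unknown)}")
    return SetSystem(groups=list(set_system.groups), selection=list(ids))


def remove_groups(set_system: SetSystem) -> SetSystem:
    """Drop all groups and the selection (idempotent)."""
    return SetSystem(groups=[], selection=[])


def format_score(score: float) -> str:
    """Display format for enrichment scores: 2 significant digits."""
    return f"{score:.2g}"
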