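"""Command interface replaying published automation workflows as scripts.

Commands are grouped in three namespaces — ``network`` (import/select),
``table`` (import) and ``examine`` (generate/select/remove groups,
update settings, export, interact) — so the workflow scripts published
for this kind of tool can be replayed in-process or from the CLI.
Every command is atomic: it either succeeds, returning an updated
session, or fails with a status naming the problem and leaves the
session untouched.
"""

from __future__ import annotations

import copy
import json
import shlex
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

from . import contours, groups, io_formats, layout
from .model import Network, NodeTable, SetSystem, Settings

__all__ = [
    "Session",
    "CommandStatus",
    "CommandError",
    "run_command",
    "run_script",
    "parse_script",
    "select_nodes",
]


class CommandError(ValueError):
    """Command failed; the session is guaranteed unchanged."""


@dataclass
class Session:
    """Mutable workflow state threaded through the command layer.

    The layout cache is invalidated by every command that changes what
    the layout depends on (network, selection of groups, settings,
    parameters), so an ``export`` never draws a stale picture.
    """

    network: Optional[Network] = None
    table: NodeTable = field(default_factory=NodeTable)
    sets: SetSystem = field(default_factory=SetSystem)
    settings: Settings = field(default_factory=Settings)
    node_selection: tuple[str, ...] = ()
    seed: int = 0
    radius: float = contours.DEFAULT_RADIUS
    layout_params: layout.LayoutParams = field(default_factory=layout.LayoutParams)
    layout_cache: Optional[layout.LayoutResult] = None

    def invalidate_layout(self) -> None:
        self.layout_cache = None

    def effective_network(self) -> Network:
        """The network that gets drawn: the induced subgraph of the node
        selection when one is active, else the full network."""
        if self.network is None:
            raise CommandError("no network imported")
        if not self.node_selection or set(self.node_selection) == self.network.node_set:
            return self.network
        chosen = set(self.node_selection)
        edges = [e for e in self.network.edges if e[0] in chosen and e[1] in chosen]
        return Network.from_edges(
            edges, extra_nodes=self.node_selection, name=self.network.name
        )

    def ensure_layout(self) -> layout.LayoutResult:
        if self.network is None or not self.network.nodes:
            raise CommandError("no network imported")
        drawn = self.effective_network()
        if not drawn.nodes:
            raise CommandError("the node selection is empty; nothing to draw")
        if self.layout_cache is None:
            params = copy.copy(self.layout_params)
            params.labels = self._labels(drawn)
            self.layout_cache = layout.compute_layout(
                drawn, self.sets, seed=self.seed, params=params
            )
        return self.layout_cache

    def _labels(self, network: Network) -> dict[str, str]:
        col = self.settings.label_column
        if col and self.table.has_column(col):
            return {n: str(self.table.cell(n, col) or n) for n in network.nodes}
        return {n: n for n in network.nodes}


@dataclass
class CommandStatus:
    """Outcome of one command: a success flag plus human-readable detail."""

    ok: bool
    namespace: str
    command: str
    messages: list[str] = field(default_factory=list)
    error: Optional[str] = None

    def __bool__(self) -> bool:
        return self.ok


def _as_bool(value, default=False) -> bool:
    if value is None:
        return default
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise CommandError(f"cannot interpret {value!r} as a boolean")


def _as_list(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v).strip() for v in value if str(v).strip()]
    return [tok.strip() for tok in str(value).split(",") if tok.strip()]


def _resolve(path_value: str, base_dir) -> Path:
    p = Path(str(path_value))
    if p.is_absolute() or base_dir is None:
        return p
    return Path(base_dir) / p


def _check_args(args: Mapping[str, object], allowed: set[str], what: str) -> None:
    unknown = sorted(set(args) - allowed)
    if unknown:
        raise CommandError(f"unknown argument(s) for {what}: {', '.join(unknown)}")


def _cmd_network_import(session: Session, args, base_dir) -> list[str]:
    _check_args(
        args,
        {"url", "path", "indexColumnSourceInteraction", "indexColumnTargetInteraction"},
        "network import",
    )
    path_value = args.get("path") or args.get("url")
    if not path_value:
        raise CommandError("network import requires a 'path' (or 'url') argument")
    if str(path_value).startswith(("http://", "https://")):
        raise CommandError(
            "remote URLs are not fetched; download the file and pass a local path"
        )
    path = _resolve(path_value, base_dir)
    if not path.exists():
        raise CommandError(f"network file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".gml":
        network = io_formats.read_gml(path)
    elif suffix == ".sif":
        network = io_formats.read_sif(path)
    else:
        src = int(args.get("indexColumnSourceInteraction", 1))
        tgt = int(args.get("indexColumnTargetInteraction", 2))
        network = io_formats.read_edge_list(path, source_column=src, target_column=tgt)
    session.network = network
    session.table = NodeTable()
    session.sets = SetSystem()
    session.node_selection = ()
    session.invalidate_layout()
    return [f"imported network: {len(network.nodes)} nodes, {len(network.edges)} edges"]


def select_nodes(session: Session, node_list: str) -> list[str]:
    """Apply a node-list spec: ``all`` or ``Column:value``.

    ``Column:value`` selects nodes whose string cell equals the value or
    whose string-list cell contains it; a value matching nothing yields
    an empty selection (not an error), an unknown column is an error.
    """
    if session.network is None:
        raise CommandError("no network imported")
    spec = str(node_list).strip()
    if spec.lower() == "all":
        session.node_selection = tuple(session.network.nodes)
        return [f"selected all {len(session.node_selection)} nodes"]
    if ":" not in spec:
        raise CommandError(
            f"node list {spec!r} is neither 'all' nor of the form 'Column:value'"
        )
    column, value = spec.split(":", 1)
    if not session.table.has_column(column):
        raise CommandError(f"unknown column in node list: {column!r}")
    col = session.table.columns[column]
    chosen = []
    for n in session.network.nodes:
        cell = col.values.get(n)
        if isinstance(cell, list):
            if value in cell:
                chosen.append(n)
        elif cell is not None and str(cell) == value:
            chosen.append(n)
    session.node_selection = tuple(chosen)
    session.invalidate_layout()
    return [f"selected {len(chosen)} node(s) matching {spec!r}"]


def _cmd_network_select(session: Session, args, base_dir) -> list[str]:
    _check_args(args, {"nodeList"}, "network select")
    if "nodeList" not in args:
        raise CommandError("network select requires a 'nodeList' argument")
    return select_nodes(session, args["nodeList"])


def _cmd_table_import(session: Session, args, base_dir) -> list[str]:
    _check_args(
        args,
        {
            "url",
            "path",
            "firstRowAsColumnNames",
            "keyColumnIndex",
            "startLoadRow",
            "dataTypeList",
        },
        "table import",
    )
    if session.network is None:
        raise CommandError("import a network before importing tables")
    path_value = args.get("path") or args.get("url")
    if not path_value:
        raise CommandError("table import requires a 'path' (or 'url') argument")
    if str(path_value).startswith(("http://", "https://")):
        raise CommandError(
            "remote URLs are not fetched; download the file and pass a local path"
        )
    path = _resolve(path_value, base_dir)
    if not path.exists():
        raise CommandError(f"table file not found: {path}")
    spec = None
    if args.get("dataTypeList"):
        spec = io_formats.parse_type_spec(str(args["dataTypeList"]))
    table = io_formats.read_node_table(
        path,
        key_column=int(args.get("keyColumnIndex", 1)),
        type_spec=spec,
        first_row_names=_as_bool(args.get("firstRowAsColumnNames"), default=True),
        start_row=int(args.get("startLoadRow", 1)),
    )
    messages = []
    node_ids = session.network.node_set
    group_ids = {g.id for g in session.sets.groups}
    node_keys = [k for k in table.row_keys if k in node_ids]
    group_keys = [k for k in table.row_keys if k in group_ids and k not in node_ids]
    orphan = [k for k in table.row_keys if k not in node_ids and k not in group_ids]

    if group_keys:
        # rows keyed by group ids annotate the groups (label/URL/score)
        sub = NodeTable(
            key=table.key,
            row_keys=tuple(group_keys),
            columns=table.columns,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unmatched handled below, jointly
            session.sets = groups.annotate_groups(
                session.sets,
                sub,
                label_column=None,
                url_column=session.settings.url_column,
                score_column=session.settings.score_column,
            )
        messages.append(f"annotated {len(group_keys)} group(s)")
    if node_keys or not group_keys:
        session.table = session.table.merge(table)
        messages.append(
            f"imported table: {len(node_keys)} row(s) matched nodes, "
            f"{len(table.columns)} column(s)"
        )
    if orphan:
        messages.append(
            f"warning: {len(orphan)} row key(s) match neither nodes nor groups"
        )
    session.invalidate_layout()
    return messages


def _cmd_generate_groups(session: Session, args, base_dir) -> list[str]:
    _check_args(
        args, {"network", "selectedGroupColumns", "useAllNodes"}, "generate groups"
    )
    if session.network is None:
        raise CommandError("no network imported")
    columns = _as_list(args.get("selectedGroupColumns"))
    if not columns:
        raise CommandError("generate groups requires 'selectedGroupColumns'")
    use_all = _as_bool(args.get("useAllNodes"), default=not session.node_selection)
    try:
        session.sets = groups.generate_groups(
            session.network,
            session.table,
            columns,
            use_all_nodes=use_all,
            selected_nodes=session.node_selection,
        )
    except groups.GroupError as exc:
        raise CommandError(str(exc)) from exc
    session.invalidate_layout()
    return [f"generated {len(session.sets.groups)} group(s) from {', '.join(columns)}"]


def _cmd_select_groups(session: Session, args, base_dir) -> list[str]:
    # published calls use both spellings of the argument; accept either
    _check_args(args, {"selectedGroup", "selectedGroups"}, "select groups")
    raw = args.get("selectedGroups", args.get("selectedGroup"))
    ids = _as_list(raw)
    try:
        session.sets = groups.select_groups(session.sets, ids)
    except groups.GroupError as exc:
        raise CommandError(str(exc)) from exc
    session.invalidate_layout()
    return [f"selected {len(ids)} group(s)"]


def _cmd_remove_groups(session: Session, args, base_dir) -> list[str]:
    _check_args(args, {"network"}, "remove groups")
    session.sets = groups.remove_groups(session.sets)
    session.invalidate_layout()
    return ["removed all groups"]


def _cmd_update_settings(session: Session, args, base_dir) -> list[str]:
    _check_args(
        args,
        {
            "network",
            "labelColumn",
            "urlColumn",
            "scoreColumn",
            "showScore",
            "selectedGroupColumns",
        },
        "update settings",
    )
    s = session.settings
    messages = []
    if "labelColumn" in args:
        s.label_column = str(args["labelColumn"]) or None
    if "urlColumn" in args:
        s.url_column = str(args["urlColumn"]) or None
    if "scoreColumn" in args:
        s.score_column = str(args["scoreColumn"]) or None
    if "showScore" in args:
        s.show_score = _as_bool(args["showScore"])
    if "selectedGroupColumns" in args:
        s.selected_group_columns = tuple(_as_list(args["selectedGroupColumns"]))
        # display filter: warn when a named column generated no groups
        generated = {g.source_column for g in session.sets.groups}
        for col in s.selected_group_columns:
            if session.sets.groups and col not in generated:
                messages.append(f"warning: column {col!r} generated no groups")
    if s.label_column and not session.table.has_column(s.label_column):
        messages.append(
            f"warning: label column {s.label_column!r} not in the node table"
        )
    session.invalidate_layout()
    return messages or ["settings updated"]


def _export_scene(session: Session) -> contours.Scene:
    result = session.ensure_layout()
    return contours.build_scene(
        session.effective_network(),
        session.sets,
        result,
        settings=session.settings,
        node_table=session.table,
        radius=session.radius,
    )


def _cmd_export(session: Session, args, base_dir) -> list[str]:
    _check_args(args, {"path"}, "export")
    if "path" not in args:
        raise CommandError("export requires a 'path' argument")
    scene = _export_scene(session)
    out = _resolve(args["path"], base_dir)
    out.parent.mkdir(parents=True, exist_ok=True)
    io_formats.write_svg(scene, out)
    return [f"wrote {out} ({len(scene.contours)} contour(s), {len(scene.nodes)} node(s))"]


def _cmd_interact(session: Session, args, base_dir) -> list[str]:
    # interactive windows are out of scope: build the scene, optionally
    # dump it to a debug SVG, and report what would be shown
    _check_args(args, {"path"}, "interact")
    scene = _export_scene(session)
    messages = [
        f"interactive view not supported; scene holds {len(scene.contours)} "
        f"contour(s) and {len(scene.nodes)} node(s)"
    ]
    if "path" in args:
        out = _resolve(args["path"], base_dir)
        out.parent.mkdir(parents=True, exist_ok=True)
        io_formats.write_svg(scene, out)
        messages.append(f"debug SVG written to {out}")
    return messages


_HANDLERS: dict[tuple[str, str], Callable] = {
    ("network", "import"): _cmd_network_import,
    ("network", "import url"): _cmd_network_import,
    ("network", "select"): _cmd_network_select,
    ("table", "import"): _cmd_table_import,
    ("table", "import url"): _cmd_table_import,
    ("examine", "generate groups"): _cmd_generate_groups,
    ("examine", "select groups"): _cmd_select_groups,
    ("examine", "remove groups"): _cmd_remove_groups,
    ("examine", "update settings"): _cmd_update_settings,
    ("examine", "export"): _cmd_export,
    ("examine", "interact"): _cmd_interact,
}


def run_command(
    session: Session,
    namespace: str,
    command: str,
    args: Mapping[str, object] | None = None,
    base_dir=None,
) -> tuple[Session, CommandStatus]:
    """Dispatch one command; atomic with respect to the session.

    Returns the updated session and a status whose ``ok`` flag mirrors
    success.  On any error the *original* session object is returned
    unchanged; the command works on a deep copy that is discarded.
    """
    args = dict(args or {})
    key = (namespace.strip().lower(), " ".join(command.strip().lower().split()))
    handler = _HANDLERS.get(key)
    if handler is None:
        return session, CommandStatus(
            ok=False,
            namespace=namespace,
            command=command,
            error=f"unknown command: {namespace} {command}",
        )
    trial = copy.deepcopy(session)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            messages = handler(trial, args, base_dir)
        messages = list(messages) + [f"warning: {w.message}" for w in caught]
    except (CommandError, io_formats.DialectError, ValueError, OSError) as exc:
        return session, CommandStatus(
            ok=False, namespace=namespace, command=command, error=str(exc)
        )
    return trial, CommandStatus(
        ok=True, namespace=namespace, command=command, messages=messages
    )


def parse_script(path) -> list[tuple[str, str, dict[str, str]]]:
    """Parse a command script.

    Text dialect: one command per line, ``namespace command... key=value
    key=value``; the command may span several words (everything before
    the first ``key=value`` token).  ``#`` lines and blank lines are
    skipped.  A file whose first non-blank character is ``[`` is parsed
    as the JSON dialect: a list of ``{"namespace":..., "command":...,
    "args": {...}}`` objects.
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("["):
        records = json.loads(text)
        return [
            (r["namespace"], r["command"], dict(r.get("args", {}))) for r in records
        ]
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = shlex.split(line)
        kv_start = next((i for i, t in enumerate(tokens) if "=" in t), len(tokens))
        if kv_start < 2:
            raise CommandError(
                f"{path}: line {lineno}: expected 'namespace command key=value...'"
            )
        namespace = tokens[0]
        command = " ".join(tokens[1:kv_start])
        args = {}
        for tok in tokens[kv_start:]:
            if "=" not in tok:
                raise CommandError(
                    f"{path}: line {lineno}: expected key=value, got {tok!r}"
                )
            k, v = tok.split("=", 1)
            args[k] = v
        out.append((namespace, command, args))
    return out


def run_script(
    session: Session,
    script_path,
    keep_going: bool = False,
    out_dir=None,
) -> tuple[Session, list[CommandStatus]]:
    """Run a command script in order.

    Input paths inside the script resolve relative to the script's
    directory; output paths (``export``/``interact``) resolve relative
    to ``out_dir`` (default: current directory).  Execution halts at the
    first error unless ``keep_going`` is set.
    """
    script_path = Path(script_path)
    if not script_path.exists():
        raise CommandError(f"script not found: {script_path}")
    records = parse_script(script_path)
    statuses: list[CommandStatus] = []
    for namespace, command, args in records:
        is_output = (namespace.lower(), command.lower()) in (
            ("examine", "export"),
            ("examine", "interact"),
        )
        base = Path(out_dir or ".") if is_output else script_path.parent
        session, status = run_command(session, namespace, command, args, base_dir=base)
        statuses.append(status)
        if not status.ok and not keep_going:
            break
    return session, statuses
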