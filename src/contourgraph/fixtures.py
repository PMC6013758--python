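"""Synthetic set-annotated graphs for tests, demos and bundled workflows.

The generator emulates the shape of the tool's typical inputs: a small
sparse connected graph whose nodes carry typed annotation columns,
including a pipe-separated string-list column encoding membership in a
handful of overlapping, connected node sets.  Two pinned builders
reproduce the shapes of the published workflows' data:

* :func:`make_karate_like` — a 34-node, 78-edge social-network stand-in
  with six overlapping communities A–F (the karate-club shape);
* :func:`make_module_fixture` — a larger interaction network containing
  a planted 17-node, 18-edge subnetwork module (``Module = small``)
  annotated with GO-term and pathway sets, plus a group-annotation
  table with labels, URLs and enrichment scores.

These are synthetic stand-ins generated by this module, not the
original tutorial datasets; they match those datasets' dialects and
headline counts so the published command sequences replay verbatim.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Column, ColumnType, Network, NodeTable

__all__ = [
    "generate_annotated_graph",
    "make_karate_like",
    "make_module_fixture",
    "write_fixture_files",
    "bundled_dir",
    "KARATE_SEED",
    "MODULE_SEED",
]

#: pinned seeds for the bundled fixture files under ``data/``
KARATE_SEED = 20
MODULE_SEED = 11


def bundled_dir() -> Path:
    """Directory holding the bundled fixture files and workflow scripts."""
    return Path(__file__).resolve().parent / "data"


def _random_tree_edges(nodes: list[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    edges = []
    for i in range(1, len(nodes)):
        j = int(rng.integers(0, i))
        edges.append((nodes[j], nodes[i]))
    return edges


def _extra_edges(
    nodes: list[str],
    existing: set[tuple[str, str]],
    edge_prob_or_count,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    candidates = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            e = (u, v) if u <= v else (v, u)
            if e not in existing:
                candidates.append(e)
    if isinstance(edge_prob_or_count, float) and edge_prob_or_count < 1.0:
        keep = rng.random(len(candidates)) < edge_prob_or_count
        return [e for e, k in zip(candidates, keep) if k]
    count = int(edge_prob_or_count)
    if count > len(candidates):
        raise ValueError(
            f"requested {count} extra edges but only {len(candidates)} are possible"
        )
    picks = rng.choice(len(candidates), size=count, replace=False)
    return [candidates[i] for i in sorted(picks)]


def _grow_patches(
    network: Network, tokens: list[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Partition nodes into connected patches by round-robin frontier growth."""
    nodes = list(network.nodes)
    adjacency = {n: [] for n in nodes}
    for u, v in network.edges:
        adjacency[u].append(v)
        adjacency[v].append(u)
    seeds = rng.choice(len(nodes), size=len(tokens), replace=False)
    owner: dict[str, str] = {}
    frontiers: dict[str, list[str]] = {}
    for tok, si in zip(tokens, seeds):
        node = nodes[int(si)]
        owner[node] = tok
        frontiers[tok] = [node]
    changed = True
    while changed:
        changed = False
        for tok in tokens:
            new_frontier = []
            claimed = None
            for node in frontiers[tok]:
                for nb in adjacency[node]:
                    if nb not in owner:
                        claimed = nb
                        break
                if claimed:
                    break
            if claimed:
                owner[claimed] = tok
                frontiers[tok].append(claimed)
                changed = True
    membership = {n: [owner[n]] if n in owner else [] for n in nodes}
    return membership


def generate_annotated_graph(
    n_nodes: int,
    edge_prob_or_count=0.08,
    n_groups: int = 4,
    overlap_fraction: float = 0.2,
    seed: int = 0,
    group_column: str = "Community",
    group_tokens: list[str] | None = None,
) -> tuple[Network, NodeTable]:
    """Random connected sparse graph with overlapping planted node sets.

    The graph is a random tree plus extra edges (``edge_prob_or_count``:
    a probability < 1 per non-tree pair, or an exact extra-edge count).
    Each of the ``n_groups`` sets is a connected node patch; about
    ``overlap_fraction`` of the nodes receive a second membership in an
    adjacent patch (so every set stays connected).  The table carries a
    ``Symbol`` (s), ``Score`` (f), ``Module`` (s) and one string-list
    membership column.  Deterministic for a fixed seed.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    if n_groups < 0:
        raise ValueError("n_groups must be non-negative")
    if n_groups > n_nodes:
        raise ValueError("cannot plant more groups than nodes")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if overlap_fraction > 0 and n_groups < 2:
        raise ValueError("overlap requires at least two groups")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes))
    nodes = [f"n{i:0{width}d}" for i in range(1, n_nodes + 1)]
    tree = _random_tree_edges(nodes, rng)
    existing = {(u, v) if u <= v else (v, u) for u, v in tree}
    extra = _extra_edges(nodes, existing, edge_prob_or_count, rng) if n_nodes > 1 else []
    network = Network.from_edges(tree + extra, extra_nodes=nodes, name=f"synthetic-{seed}")

    tokens = list(group_tokens) if group_tokens else [
        chr(ord("A") + i) for i in range(n_groups)
    ]
    if len(tokens) != n_groups:
        raise ValueError("group_tokens length must equal n_groups")
    if n_groups > 0:
        membership = _grow_patches(network, tokens, rng)
        adjacency = {n: network.neighbors(n) for n in nodes}
        target = round(overlap_fraction * n_nodes)
        order = list(rng.permutation(n_nodes))
        added = 0
        for i in order:
            if added >= target:
                break
            node = nodes[int(i)]
            mine = set(membership[node])
            neighbor_tokens = sorted(
                {t for nb in adjacency[node] for t in membership[nb]} - mine
            )
            if not neighbor_tokens:
                continue
            pick = neighbor_tokens[int(rng.integers(0, len(neighbor_tokens)))]
            membership[node].append(pick)
            added += 1
    else:
        membership = {n: [] for n in nodes}

    table = NodeTable(
        key="name",
        row_keys=tuple(nodes),
        columns={
            "Symbol": Column(
                ColumnType.STRING, {n: n.upper() for n in nodes}
            ),
            "Score": Column(
                ColumnType.FLOAT,
                {n: round(float(rng.normal(0.0, 2.0)), 3) for n in nodes},
            ),
            "Module": Column(ColumnType.STRING, {n: "" for n in nodes}),
            group_column: Column(
                ColumnType.STRING_LIST, {n: list(membership[n]) for n in nodes}
            ),
        },
    )
    return network, table


def make_karate_like(seed: int = KARATE_SEED) -> tuple[Network, NodeTable]:
    """34-node, 78-edge network with six overlapping communities A-F.

    Shape-matched synthetic stand-in for the karate-club workflow input:
    the node table has the key column plus a single ``Community``
    string-list column (table dialect ``s,sl``).
    """
    network, table = generate_annotated_graph(
        n_nodes=34,
        edge_prob_or_count=78 - 33,  # random tree has 33 edges
        n_groups=6,
        overlap_fraction=0.2,
        seed=seed,
        group_column="Community",
    )
    slim = NodeTable(
        key="name",
        row_keys=table.row_keys,
        columns={"Community": table.columns["Community"]},
    )
    return network, slim


#: planted annotation sets of the module fixture: column -> token -> label
MODULE_SETS = {
    "Component": {
        "GO:0005737": "cytoplasm",
        "GO:0016020": "membrane",
    },
    "Function": {
        "GO:0008013": "beta-catenin binding",
        "GO:0008083": "growth factor activity",
        "GO:0019899": "enzyme binding",
    },
    "Pathway": {
        "mmu04070": "Phosphatidylinositol signaling system",
        "mmu05200": "Pathways in cancer",
        "mmu04520": "Adherens junction",
    },
    "Process": {
        "GO:0006915": "apoptotic process",
    },
}

MODULE_SIZE = 17
MODULE_EDGES = 18


def _connected_patch(
    start: str, size: int, adjacency: dict[str, list[str]], rng: np.random.Generator
) -> list[str]:
    patch = [start]
    frontier = set(adjacency[start])
    while len(patch) < size and frontier:
        pick = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        patch.append(pick)
        frontier.update(adjacency[pick])
        frontier -= set(patch)
    return patch


def make_module_fixture(
    seed: int = MODULE_SEED, n_nodes: int = 40
) -> tuple[Network, NodeTable, NodeTable]:
    """Interaction network with a planted 17-node, 18-edge module.

    Returns (network, node table, group-annotation table).  The node
    table has the 12-column dialect ``s,s,f,f,f,s,s,s,sl,sl,sl,sl``:
    name, Symbol, Score, LogFC, PValue, URL, Module, Organism and four
    string-list set columns (Component, Function, Pathway, Process).
    ``Module`` is ``small`` exactly on the planted module, whose induced
    subgraph has exactly 18 edges by construction.  The annotation sets
    live on module nodes (one decoy token sits outside the module to
    exercise scope restriction); the group table carries Label, URL and
    a synthetic enrichment Score per set.
    """
    if n_nodes < MODULE_SIZE + 3:
        raise ValueError("module fixture needs some non-module nodes")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes))
    nodes = [f"g{i:0{width}d}" for i in range(1, n_nodes + 1)]
    module_nodes = nodes[:MODULE_SIZE]
    rest = nodes[MODULE_SIZE:]

    # module: random tree (16 edges) + 2 chords = exactly 18 induced edges
    module_edges = _random_tree_edges(module_nodes, rng)
    existing = {(u, v) if u <= v else (v, u) for u, v in module_edges}
    module_edges += _extra_edges(module_nodes, existing, MODULE_EDGES - (MODULE_SIZE - 1), rng)
    # the rest: its own random tree, plus bridges into the module
    rest_edges = _random_tree_edges(rest, rng)
    bridges = [
        (rest[int(rng.integers(0, len(rest)))], module_nodes[int(rng.integers(0, MODULE_SIZE))])
        for _ in range(3)
    ]
    network = Network.from_edges(
        module_edges + rest_edges + bridges, extra_nodes=nodes, name="module-fixture"
    )

    adjacency = {n: [] for n in module_nodes}
    for u, v in module_edges:
        adjacency[u].append(v)
        adjacency[v].append(u)

    membership: dict[str, dict[str, list[str]]] = {
        col: {n: [] for n in nodes} for col in MODULE_SETS
    }
    for col, tokens in MODULE_SETS.items():
        for token in tokens:
            size = int(rng.integers(3, 8))
            start = module_nodes[int(rng.integers(0, MODULE_SIZE))]
            for member in _connected_patch(start, size, adjacency, rng):
                membership[col][member].append(token)
    # decoy: a set token on a non-module node; module-scoped group
    # generation must not pick it up
    membership["Function"][rest[0]].append("GO:0008013")

    symbols = [f"Gene{i}" for i in range(1, n_nodes + 1)]
    table = NodeTable(
        key="name",
        row_keys=tuple(nodes),
        columns={
            "Symbol": Column(ColumnType.STRING, dict(zip(nodes, symbols))),
            "Score": Column(
                ColumnType.FLOAT,
                {n: round(float(rng.normal(0.0, 3.0)), 3) for n in nodes},
            ),
            "LogFC": Column(
                ColumnType.FLOAT,
                {n: round(float(rng.normal(0.0, 1.5)), 3) for n in nodes},
            ),
            "PValue": Column(
                ColumnType.FLOAT,
                {n: round(float(rng.uniform(1e-6, 0.05)), 6) for n in nodes},
            ),
            "URL": Column(
                ColumnType.STRING,
                {n: f"https://example.org/gene/{s}" for n, s in zip(nodes, symbols)},
            ),
            "Module": Column(
                ColumnType.STRING,
                {n: ("small" if n in set(module_nodes) else "") for n in nodes},
            ),
            "Organism": Column(ColumnType.STRING, {n: "mouse" for n in nodes}),
            **{
                col: Column(
                    ColumnType.STRING_LIST, {n: list(membership[col][n]) for n in nodes}
                )
                for col in MODULE_SETS
            },
        },
    )

    set_ids = [tok for tokens in MODULE_SETS.values() for tok in tokens]
    labels = {tok: lab for tokens in MODULE_SETS.values() for tok, lab in tokens.items()}
    group_table = NodeTable(
        key="name",
        row_keys=tuple(set_ids),
        columns={
            "Label": Column(ColumnType.STRING, {t: labels[t] for t in set_ids}),
            "URL": Column(
                ColumnType.STRING,
                {
                    t: (
                        f"https://www.genome.jp/pathway/{t}"
                        if t.startswith("mmu")
                        else f"https://amigo.geneontology.org/amigo/term/{t}"
                    )
                    for t in set_ids
                },
            ),
            "Score": Column(
                ColumnType.FLOAT,
                {t: round(float(rng.uniform(1.5, 9.0)), 2) for t in set_ids},
            ),
        },
    )
    return network, table, group_table


def write_fixture_files(
    network: Network,
    table: NodeTable,
    directory,
    group_table: NodeTable | None = None,
    basename: str = "fixture",
    gml: bool = True,
) -> dict[str, Path]:
    """Write a fixture in every reader dialect; returns written paths.

    Emits ``<basename>_edges.txt`` (relation/source/target columns),
    optionally ``<basename>.gml``, ``<basename>_nodes.txt`` and, when a
    group table is given, ``<basename>_sets.txt``.  Reading the files
    back reproduces the in-memory fixture exactly.
    """
    from . import io_formats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edges_path = directory / f"{basename}_edges.txt"
    io_formats.write_edge_list(network, edges_path)
    paths["edges"] = edges_path

    if gml:
        import networkx as nx

        gml_path = directory / f"{basename}.gml"
        nx.write_gml(network.to_networkx(), gml_path)
        paths["gml"] = gml_path

    nodes_path = directory / f"{basename}_nodes.txt"
    io_formats.write_node_table(table, nodes_path)
    paths["nodes"] = nodes_path

    if group_table is not None:
        sets_path = directory / f"{basename}_sets.txt"
        io_formats.write_node_table(group_table, sets_path)
        paths["sets"] = sets_path
    return paths
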