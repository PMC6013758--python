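# Methods

## Problem and model

The input is a small undirected graph (tens of nodes; identifiers are
opaque case-sensitive strings) plus typed node annotations, among them
*string-list* columns whose pipe-separated tokens encode membership in
overlapping node sets ("groups"): enriched GO terms or KEGG pathways
over a subnetwork module, communities in a social network. The output
is an SVG: a node-link drawing in which each *selected* group is a
translucent rounded region covering exactly its members' glyphs.

The drawing model has three coupled parts.

**Layout as stress minimization.** Target distances are graph-theoretic:
`d(u,v)` = unit-weight all-pairs shortest paths. The layout minimizes
weighted stress `Σ_{u<v} w_uv (‖p_u − p_v‖ − L·d_uv)²` with
`w_uv = (L·d_uv)⁻²`, the standard inverse-square weighting that
prioritizes short-range fidelity. Minimization is SMACOF: the Guttman
transform `X ← V⁺ B(X) X` with the weight Laplacian `V` pseudo-inverted
once per layout. Each transform step is a majorization step, so stress
is non-increasing at every iteration — asserted in the test suite, not
assumed. Iteration stops when the relative stress drop falls below
1e−6 or after 300 iterations.

**Set attraction via spanning trees.** For each selected group a
minimum spanning tree is computed on the complete graph over its
members, weighted by the base distances (Kruskal; ties broken by
lexicographic (weight, endpoint) order, so the tree is deterministic).
Tree links scaled by the attraction factor `α = 0.7` are added as
weighted shortcut links and the shortest-path distances are recomputed,
shortening targets among members and pulling them together in the
layout. Trees span members only (no Steiner routing through
non-members): member-only trees keep the contour skeleton inside the
set and make the tree a pure function of the member list and the
distance matrix. Groups with members outside the currently drawn
(sub)network are silently restricted to the drawn members.

**Contours from inflated trees.** A group's contour is the union of (a)
discs of radius `r + c_m` at each member `m`, where `c_m` is the
circumradius of the member's glyph rectangle (so the glyph fits
strictly inside), and (b) bands of half-width `r` along each tree link,
with rounded caps. The union of discs centered on the link endpoints
with the link bands is connected, so a tree skeleton yields exactly one
closed boundary ring (interior rings — holes — are kept if the union
produces them). Circles are approximated with 64 segments (shapely
`quad_segs=16`); the inscribed-polygon area deficit at that resolution
is ≈0.16%, comfortably inside the 1% tolerance the geometry tests use.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 0.7 | – | scale on injected spanning-tree links; < 1 attracts members |
| `edge_length` | 80 | layout units / hop | converts hop distances to drawing units, sized so one hop clears two typical glyphs |
| `max_iter` | 300 | iterations | majorization cap |
| `tol` | 1e−6 | – | relative stress-change convergence threshold |
| `padding` | 2 | layout units | added to rectangle extents in the overlap test |
| `radius` | 14 | layout units | contour inflation half-width |
| glyph width | 7·len(label)+10 | layout units | monospace label-box approximation |
| glyph height | 18 | layout units | one text line |
| `seed` | 0 | – | initial placement; identical seed + input ⇒ bit-identical output |

`alpha`, `edge_length`, the glyph metrics, the surrogate-distance
factor (below) and `radius` are this package's own calibration; they
are exposed as parameters rather than baked in.

## Numerical and degenerate-input choices

- **Initial placement**: seeded uniform random in `[0, √n]²` (scaled by
  `edge_length`), via `numpy.random.default_rng(seed)`.
- **Disconnected graphs**: infinite shortest-path distances are
  replaced by 1.5× the finite diameter (1.0 if no finite off-diagonal
  distance exists), keeping components nearby but separated.
- **Coincident points in SMACOF**: pairs at zero realized distance
  contribute no direction (the standard subgradient choice); the
  majorization guarantee is unaffected.
- **Single node**: placed at the origin, no iterations.
- **Overlap removal**: pairs are visited in node order; an overlapping
  pair is split along the axis requiring the smaller displacement,
  half each way; exactly coincident centers split along x. Pure
  pairwise pushing can cycle on dense piles, so every 20th
  still-overlapping sweep also spreads all positions 5% outward from
  the centroid — a deterministic escalation that preserves the layout's
  shape while guaranteeing progress. If 200 sweeps do not suffice the
  result is returned best-so-far with `overlap_converged = False` and a
  warning; every converged run is verifiably overlap-free.
- **Float cells** that fail to parse, and non-finite floats, become
  missing values with a warning rather than errors; width mismatches
  and unknown type tokens are hard errors with line/position numbers.
- **Group-id collisions** across two source columns keep the bare token
  for the first column and qualify the second as `column:token`,
  because published selection commands address groups by bare token.
- **Scores** display with 2 significant digits.
- **Equal source/target column indices** in an edge-list import (which
  appear verbatim in published command calls but cannot address two
  endpoint columns) are accommodated as `(k, k+1)` with a warning.

## Command layer

Commands are atomic: each runs on a deep copy of the session and either
commits or reports an error, so a failed command can never corrupt
state (tested by injecting failures and deep-comparing). `table import`
routes rows by key — node-id rows merge into the node table, group-id
rows annotate groups — mirroring tools that keep both in one table.
When a node selection is active, export draws the induced subgraph of
the selection; group generation defaults to the selection scope when
one exists (`useAllNodes` overrides). Both `selectedGroup` and
`selectedGroups` argument spellings are accepted, as published
workflows use both. A visualization-settings command naming a group
column that generated no groups warns instead of failing, since such
inconsistencies occur in published scripts. `interact` builds the scene
and optionally writes a debug SVG; interactive windows are out of
scope. Only single-network sessions are supported; multi-network
arguments are accepted and ignored.

## Synthetic data

`fixtures.generate_annotated_graph` emulates the tool's typical inputs:
a connected sparse graph (random tree plus extra edges), node sets
planted as *connected* patches (grown by round-robin multi-source BFS),
and a controlled fraction of nodes carrying a second membership in an
adjacent patch (so overlap never disconnects a set). Two pinned
builders bundle text fixtures under `src/contourgraph/data/`:

- `make_karate_like` — 34 nodes, exactly 78 edges, six overlapping
  communities A–F, table dialect `s,sl`;
- `make_module_fixture` — a 40-node network containing a planted
  17-node module whose induced subgraph has exactly 18 edges **by
  construction** (module tree + 2 chords; bridges to the rest leave the
  induced count fixed), annotated with GO/pathway-style sets in the
  12-column dialect `s,s,f,f,f,s,s,s,sl,sl,sl,sl`, plus a set table
  with labels, URLs and synthetic enrichment scores. One decoy set
  token sits outside the module to exercise scope restriction.

These are synthetic stand-ins, not the original tutorial or
karate-club data. They reproduce the dialects, the headline counts and
the overlap structure, so workflow replays and count checks are
meaningful; they do not reproduce degree distributions, community sizes
or any biological signal, so passing tests say nothing about layout
aesthetics on real interaction networks. Enrichment scores are drawn
uniformly and are display-only — computing enrichment is upstream of
this tool.

## Problem sizes

The test suite and the acceptance script run at the scale the tool
targets: graphs of 12–40 nodes, 50 seeded layouts for the overlap
guarantee, 10 runs for stress monotonicity, 5 paired runs for the
set-attraction comparison. The whole suite completes in a few seconds.

## Known limitations

- Suitable for small, relatively sparse networks only; the dense
  all-pairs formulation scales as O(n²)–O(n³) and contour clutter grows
  quickly with dozens of sets.
- Non-member exclusion from a contour is best-effort: the layout pulls
  members together, but a non-member lying between two members can be
  enclosed. Exclusion is only guaranteed (and only asserted) for nodes
  farther than the inflation radius plus glyph clearance from every
  member and tree link.
- Contour–contour avoidance is not attempted; overlapping regions are
  alpha-blended.
- Glyph metrics are a monospace approximation, not font metrics; SVG
  renderers with very different fonts may show labels slightly
  overflowing their boxes.
- Remote URLs are not fetched; all readers take local paths.
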