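"""The multi-resolution cluster-flow directed acyclic graph.

Each column of the graph is the community structure at one resolution
parameter; nodes are clusters scaled by cell count, and edges ("flows")
carry the cells a source cluster at resolution ``j`` hands to a target
cluster at the next grid resolution.  Because edges only ever point to the
adjacent column, the structure is acyclic by construction, and exact
conservation holds: an interior node's size equals both the sum of its
incoming and of its outgoing flow counts.

Cluster labels are size-ordered per column (label 0 is the largest
cluster), matching the numbering convention of modularity-based
single-cell pipelines, and node identifiers are ``"<resolution>_<label>"``
with the resolution string preserved from the input header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CellAssignmentMatrix

_log = logging.getLogger("cellflows.graph")

__all__ = [
    "ClusterNode",
    "Flow",
    "SankeyGraph",
    "relabel_by_size",
    "size_rank_column",
    "build_nodes",
    "compute_flows",
    "build_graph",
    "layout_graph",
    "count_crossings",
]


@dataclass
class ClusterNode:
    """One cluster at one resolution."""

    resolution: float
    resolution_name: str
    label: int
    member_index: np.ndarray  # indices into the canonical cell order
    annotations: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(self.member_index.size)

    @property
    def node_id(self) -> str:
        return f"{self.resolution_name}_{self.label}"


@dataclass
class Flow:
    """Cells shared between a cluster and one cluster in the next column."""

    source: str
    target: str
    count: int
    member_index: np.ndarray
    forward_prop: float   # count / size(source)
    backward_prop: float  # count / size(target)
    paint: dict = field(default_factory=dict)

    @property
    def mutual_prop(self) -> float:
        return min(self.forward_prop, self.backward_prop)


@dataclass
class SankeyGraph:
    resolutions: np.ndarray
    resolution_names: list[str]
    cell_ids: list[str]
    columns: list[list[ClusterNode]]        # per resolution, label-ordered
    flows: list[Flow]
    layout: dict[str, dict] = field(default_factory=dict)  # node_id -> x, y, height

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def nodes(self) -> list[ClusterNode]:
        return [nd for col in self.columns for nd in col]

    def node(self, node_id: str) -> ClusterNode:
        return self._index()[node_id]

    def _index(self) -> dict[str, ClusterNode]:
        if not hasattr(self, "_node_index") or len(self._node_index) != sum(
            len(c) for c in self.columns
        ):
            self._node_index = {nd.node_id: nd for nd in self.nodes}
        return self._node_index

    def flows_between(self, j: int) -> list[Flow]:
        """Flows leaving column ``j`` (into column ``j + 1``)."""
        prefix = self.resolution_names[j] + "_"
        return [f for f in self.flows if f.source.startswith(prefix)]

    def validate(self) -> None:
        """Check the structural invariants (partition, conservation, acyclicity)."""
        n = self.n_cells
        index = self._index()
        for col in self.columns:
            sizes = [nd.size for nd in col]
            if sum(sizes) != n:
                raise ValueError("column sizes do not sum to the cell count")
            if any(s == 0 for s in sizes):
                raise ValueError("empty cluster node")
            if sizes != sorted(sizes, reverse=True):
                raise ValueError("labels are not size-ordered within a column")
        col_of = {
            nd.node_id: j for j, col in enumerate(self.columns) for nd in col
        }
        incoming: dict[str, int] = {nid: 0 for nid in index}
        outgoing: dict[str, int] = {nid: 0 for nid in index}
        for f in self.flows:
            if col_of[f.target] != col_of[f.source] + 1:
                raise ValueError("flow does not connect adjacent columns")
            if f.count < 1 or f.count != f.member_index.size:
                raise ValueError("flow count does not match its member set")
            outgoing[f.source] += f.count
            incoming[f.target] += f.count
        last = len(self.columns) - 1
        for nd in self.nodes:
            j = col_of[nd.node_id]
            if j < last and outgoing[nd.node_id] != nd.size:
                raise ValueError(f"outgoing flows of {nd.node_id} do not conserve size")
            if j > 0 and incoming[nd.node_id] != nd.size:
                raise ValueError(f"incoming flows of {nd.node_id} do not conserve size")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def size_rank_column(col: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel one column by descending cluster size (ties keep label order)."""
    uniq, counts = np.unique(col, return_counts=True)
    order = np.lexsort((uniq, -counts))  # by descending size, then label
    mapping = {int(uniq[o]): rank for rank, o in enumerate(order)}
    return np.vectorize(mapping.__getitem__, otypes=[np.int64])(col), mapping


def relabel_by_size(assign: CellAssignmentMatrix) -> CellAssignmentMatrix:
    """Permute labels per column so lower labels mean larger clusters.

    The partition is unchanged; the ``{original: new}`` map per column is
    retained on the returned matrix.  Size ties keep the original label
    order, which makes the operation idempotent.
    """
    labels = assign.labels.copy()
    maps: list[dict[int, int]] = []
    for j in range(labels.shape[1]):
        labels[:, j], mapping = size_rank_column(labels[:, j])
        maps.append(mapping)
    return CellAssignmentMatrix(
        cell_ids=list(assign.cell_ids),
        resolutions=assign.resolutions.copy(),
        labels=labels,
        resolution_names=list(assign.resolution_names),
        label_maps=maps,
    )


def build_nodes(assign: CellAssignmentMatrix) -> list[list[ClusterNode]]:
    """One node per (resolution, observed label); member sets partition each column."""
    columns: list[list[ClusterNode]] = []
    for j in range(assign.n_resolutions):
        col = assign.column(j)
        nodes = [
            ClusterNode(
                resolution=float(assign.resolutions[j]),
                resolution_name=assign.resolution_names[j],
                label=int(lab),
                member_index=np.flatnonzero(col == lab),
            )
            for lab in np.unique(col)
        ]
        columns.append(nodes)
    return columns


def compute_flows(assign: CellAssignmentMatrix, j: int) -> list[Flow]:
    """Flows between adjacent columns ``j`` and ``j + 1``.

    Exactly the nonzero cells of the source-label x target-label
    contingency table; member sets are the label-pair intersections.
    """
    if not 0 <= j < assign.n_resolutions - 1:
        raise ValueError(f"no column pair ({j}, {j + 1}) in the grid")
    src, tgt = assign.column(j), assign.column(j + 1)
    src_sizes = dict(zip(*np.unique(src, return_counts=True)))
    tgt_sizes = dict(zip(*np.unique(tgt, return_counts=True)))
    pairs = src.astype(np.int64) * (tgt.max() + 1) + tgt
    flows = []
    for code in np.unique(pairs):
        members = np.flatnonzero(pairs == code)
        a, b = divmod(int(code), int(tgt.max() + 1))
        flows.append(
            Flow(
                source=f"{assign.resolution_names[j]}_{a}",
                target=f"{assign.resolution_names[j + 1]}_{b}",
                count=members.size,
                member_index=members,
                forward_prop=members.size / src_sizes[a],
                backward_prop=members.size / tgt_sizes[b],
            )
        )
    flows.sort(key=lambda f: (f.source, f.target))
    return flows


def build_graph(assign: CellAssignmentMatrix, relabel: bool = True) -> SankeyGraph:
    """Assemble the full graph from an assignment matrix.

    Labels are size-ordered first (skip with ``relabel=False`` if the
    matrix already is).  Requires at least two resolutions; a single
    column admits no flows.
    """
    if assign.n_resolutions < 2:
        raise ValueError("at least 2 resolutions are required to build flows")
    if relabel:
        assign = relabel_by_size(assign)
    columns = build_nodes(assign)
    flows: list[Flow] = []
    for j in range(assign.n_resolutions - 1):
        flows.extend(compute_flows(assign, j))
    g = SankeyGraph(
        resolutions=assign.resolutions.copy(),
        resolution_names=list(assign.resolution_names),
        cell_ids=list(assign.cell_ids),
        columns=columns,
        flows=flows,
    )
    g.validate()
    layout_graph(g)
    return g


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


def count_crossings(g: SankeyGraph, orders: list[list[str]]) -> int:
    """Number of crossing flow pairs under the given per-column node orders."""
    pos = [{nid: i for i, nid in enumerate(col)} for col in orders]
    total = 0
    for j in range(len(g.columns) - 1):
        edges = [
            (pos[j][f.source], pos[j + 1][f.target])
            for f in g.flows_between(j)
        ]
        for a in range(len(edges)):
            for b in range(a + 1, len(edges)):
                (s1, t1), (s2, t2) = edges[a], edges[b]
                if (s1 - s2) * (t1 - t2) < 0:
                    total += 1
    return total


def layout_graph(g: SankeyGraph, iterations: int = 4, gap: float = 0.05) -> dict[str, dict]:
    """Assign x/y/height to every node with a crossing-reducing ordering.

    Within-column vertical order comes from barycenter sweeps: alternating
    left-to-right and right-to-left passes in which each node moves to the
    flow-count-weighted mean position of its neighbours in the fixed
    adjacent column (ties broken by node label, so the result is
    deterministic).  The ordering kept is the best seen over all sweeps, so
    the final crossing count is never worse than the initial size-order
    layout.  x is the column index scaled to [0, 1]; heights are
    proportional to size with ``gap`` of the total height shared between
    the gaps of each column.
    """
    ncols = len(g.columns)
    orders: list[list[str]] = [[nd.node_id for nd in col] for col in g.columns]
    out_adj: list[dict[str, list[tuple[str, int]]]] = [dict() for _ in range(ncols)]
    in_adj: list[dict[str, list[tuple[str, int]]]] = [dict() for _ in range(ncols)]
    for j in range(ncols - 1):
        for f in g.flows_between(j):
            out_adj[j].setdefault(f.source, []).append((f.target, f.count))
            in_adj[j + 1].setdefault(f.target, []).append((f.source, f.count))

    label_of = {nd.node_id: nd.label for nd in g.nodes}

    def sweep_column(j: int, adj: dict[str, list[tuple[str, int]]], ref_order: list[str]) -> None:
        ref_pos = {nid: i for i, nid in enumerate(ref_order)}
        current = {nid: i for i, nid in enumerate(orders[j])}

        def barycenter(nid: str) -> float:
            nbrs = adj.get(nid, [])
            if not nbrs:
                return float(current[nid])
            w = sum(c for _, c in nbrs)
            return sum(ref_pos[t] * c for t, c in nbrs) / w

        orders[j] = sorted(orders[j], key=lambda nid: (barycenter(nid), label_of[nid]))

    best = [list(c) for c in orders]
    best_crossings = count_crossings(g, orders)
    for _ in range(iterations):
        for j in range(1, ncols):          # left-to-right
            sweep_column(j, in_adj[j], orders[j - 1])
        for j in range(ncols - 2, -1, -1):  # right-to-left
            sweep_column(j, out_adj[j], orders[j + 1])
        c = count_crossings(g, orders)
        if c < best_crossings:
            best_crossings, best = c, [list(col) for col in orders]
    orders = best

    n = g.n_cells
    layout: dict[str, dict] = {}
    for j, col_order in enumerate(orders):
        x = 0.0 if ncols == 1 else j / (ncols - 1)
        k = len(col_order)
        gap_each = gap / (k - 1) if k > 1 else 0.0
        y = 0.0
        sizes = {nd.node_id: nd.size for nd in g.columns[j]}
        for nid in col_order:
            h = (1.0 - gap) * sizes[nid] / n
            layout[nid] = {"x": x, "y": y, "height": h}
            y += h + gap_each
    g.layout = layout
    return layout
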