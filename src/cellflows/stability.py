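"""Tracing stable cell communities across the resolution grid.

A flow is *stable* when its mutual proportion — the flow's cell count
divided by the larger requirement of its two endpoints, i.e.
``min(count / size(source), count / size(target))`` — reaches a threshold
tau.  The definition is symmetric in the two endpoints, and for
tau > 0.5 the pigeonhole principle guarantees at most one stable flow in
and one out of every node, so stable flows chain into well-defined,
node-disjoint paths.

A :class:`StablePath` is a maximal chain of stable flows: a cell
community that keeps (at least fraction tau of) its membership as the
resolution changes.  Its score is the weakest mutual proportion along the
chain and its *core* is the cell set shared by every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .graph import Flow, SankeyGraph

_log = logging.getLogger("cellflows.stability")

__all__ = ["StablePath", "DEFAULT_TAU", "stable_flows", "trace_paths"]

DEFAULT_TAU = 0.9


@dataclass
class StablePath:
    """A maximal chain of stable flows across consecutive columns."""

    node_ids: list[str]      # >= 2 nodes in consecutive columns
    flows: list[Flow]        # len(node_ids) - 1 steps
    stability: float         # min over steps of mutual proportion
    core_index: np.ndarray   # cells present in every step of the chain

    @property
    def span(self) -> int:
        return len(self.node_ids)

    @property
    def core_size(self) -> int:
        return int(self.core_index.size)


def stable_flows(g: SankeyGraph, tau: float = DEFAULT_TAU) -> list[Flow]:
    """Flows whose mutual proportion reaches ``tau``."""
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    return [f for f in g.flows if f.mutual_prop >= tau]


def trace_paths(g: SankeyGraph, tau: float = DEFAULT_TAU) -> list[StablePath]:
    """Maximal chains of stable flows.

    Chains start at nodes with no stable incoming flow and extend greedily
    forward; when tau > 0.5 each node has at most one stable flow in either
    direction, so the chains are node-disjoint and uniquely determined.
    For smaller tau, branches are resolved deterministically in favour of
    the higher mutual proportion (then larger count, then target id), and
    each flow belongs to at most one path.

    Output is sorted by span length, then core size (both descending),
    then first node id.
    """
    flows = stable_flows(g, tau)
    out_of: dict[str, list[Flow]] = {}
    has_incoming: set[str] = set()
    for f in flows:
        out_of.setdefault(f.source, []).append(f)
        has_incoming.add(f.target)
    for lst in out_of.values():
        lst.sort(key=lambda f: (-f.mutual_prop, -f.count, f.target))

    col_of = {nd.node_id: j for j, col in enumerate(g.columns) for nd in col}
    starts = sorted(
        (nid for nid in out_of if nid not in has_incoming),
        key=lambda nid: (col_of[nid], nid),
    )

    used: set[int] = set()
    paths: list[StablePath] = []
    for start in starts:
        chain: list[Flow] = []
        current = start
        while True:
            nxt = next((f for f in out_of.get(current, []) if id(f) not in used), None)
            if nxt is None:
                break
            used.add(id(nxt))
            chain.append(nxt)
            current = nxt.target
        if not chain:
            continue
        core = reduce(np.intersect1d, (f.member_index for f in chain))
        paths.append(
            StablePath(
                node_ids=[chain[0].source] + [f.target for f in chain],
                flows=chain,
                stability=min(f.mutual_prop for f in chain),
                core_index=core,
            )
        )
    paths.sort(key=lambda p: (-p.span, -p.core_size, p.node_ids[0]))
    return paths
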