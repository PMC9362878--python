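"""Flow painting: single-gene mean expression and 3-gene co-expression.

The co-expression statistic is the gene expression percentage (GEP).  For
an ordered geneset E of n = 3 genes and a flow of m cells,

    GEP_i = ( sum_{j=1..m} E_{i,j} ) / ( sum_{j=1..m} sum_{k=1..n} E_{k,j} )

i.e. each gene's summed expression over the flow's cells divided by the
summed expression of the whole geneset over those cells.  The three
fractions sum to one and serve both as barycentric ternary-chart
coordinates and as RGB channels (first gene -> red, second -> green,
third -> blue).  A flow in which the geneset is entirely silent has an
undefined GEP and is painted a neutral gray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import Flow, SankeyGraph
from .io import ExpressionMatrix

_log = logging.getLogger("cellflows.overlays")

__all__ = [
    "GeneSet",
    "GEPTriple",
    "TernaryPoint",
    "NEUTRAL_HEX",
    "flow_mean_expression",
    "compute_gep",
    "gep_to_hex",
    "paint_flows_expression",
    "paint_flows_gep",
    "ternary_dataset",
]

NEUTRAL_HEX = "#BEBEBE"
POINT_SIZE_SCALAR = 2.0  # ternary point size = scalar * log2(flow cell count)


@dataclass(frozen=True)
class GeneSet:
    """Ordered gene ids; exactly 3 for co-expression, 1 for expression painting."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in geneset")
        if not self.genes:
            raise ValueError("empty geneset")

    def require_triple(self) -> None:
        if len(self.genes) != 3:
            raise ValueError("co-expression requires exactly 3 genes")

    def check_present(self, expr: ExpressionMatrix) -> None:
        for g in self.genes:
            expr.gene_column(g)  # raises with near-matches if unknown


@dataclass(frozen=True)
class GEPTriple:
    """Per-flow co-expression fractions; ``defined`` is False when the
    geneset has zero total expression over the flow."""

    fractions: tuple[float, float, float]
    defined: bool

    def __post_init__(self) -> None:
        if self.defined:
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("defined GEP fractions must sum to 1")
            if any(f < 0 or f > 1 for f in self.fractions):
                raise ValueError("GEP fractions must lie in [0, 1]")


@dataclass
class TernaryPoint:
    """One ternary-chart point per flow with a defined GEP.

    ``size`` is ``2 * log2(m)`` for a flow of m cells; single-cell flows
    store the true value 0 and are rendered at a 1-px floor.
    """

    source: str
    target: str
    gep: GEPTriple
    count: int
    size: float
    color: str


# ---------------------------------------------------------------------------
# Per-flow statistics
# ---------------------------------------------------------------------------


def flow_mean_expression(flow: Flow, expr: ExpressionMatrix, gene: str) -> float:
    """Arithmetic mean of one gene's expression over the flow's cells."""
    if flow.count == 0:
        raise ValueError("empty flow")
    vec = expr.gene_vector(gene)
    return float(vec[flow.member_index].mean())


def compute_gep(flow: Flow, expr: ExpressionMatrix, genes: GeneSet) -> GEPTriple:
    """Gene expression percentages of an ordered 3-gene set over a flow."""
    genes.require_triple()
    if flow.count == 0:
        raise ValueError("empty flow")
    block = expr.submatrix(flow.member_index, list(genes.genes))
    per_gene = block.sum(axis=0)
    total = float(per_gene.sum())
    if total == 0.0:
        return GEPTriple(fractions=(0.0, 0.0, 0.0), defined=False)
    f = per_gene / total
    return GEPTriple(fractions=(float(f[0]), float(f[1]), float(f[2])), defined=True)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def gep_to_hex(t: GEPTriple, neutral: str = NEUTRAL_HEX) -> str:
    """Map a GEP triple to ``#RRGGBB``: channel_i = round(255 * GEP_i).

    Rounding is half-away-from-zero; an undefined triple maps to the
    neutral color.
    """
    if not t.defined:
        return neutral
    channels = [_round_half_away(255.0 * f) for f in t.fractions]
    return "#{:02X}{:02X}{:02X}".format(*channels)


# ---------------------------------------------------------------------------
# Graph-level painting
# ---------------------------------------------------------------------------


def _colormap(name: str):
    import matplotlib

    try:
        return matplotlib.colormaps[name]
    except KeyError:
        raise ValueError(f"unknown colormap {name!r}") from None


def _to_hex(rgba) -> str:
    r, g, b = (int(round(255 * c)) for c in rgba[:3])
    return f"#{r:02X}{g:02X}{b:02X}"


def paint_flows_expression(
    g: SankeyGraph,
    expr: ExpressionMatrix,
    gene: str,
    colormap: str = "viridis",
    scale: str = "global",
    overlay_name: str | None = None,
) -> str:
    """Paint every flow by the gene's mean expression through a colormap.

    Raw means are min-max normalized — over all flows (``scale="global"``)
    or within each column pair (``scale="per-column"``) — then looked up in
    the named colormap.  A degenerate (constant) range maps to the colormap
    midpoint.  Both the raw value and the hex color are stored under
    ``flow.paint[overlay]``; the overlay name is returned.
    """
    cmap = _colormap(colormap)
    if scale not in ("global", "per-column"):
        raise ValueError(f"unknown scale {scale!r}")
    overlay = overlay_name or f"expr:{gene}"
    raw = {id(f): flow_mean_expression(f, expr, gene) for f in g.flows}

    def paint_group(flows: list[Flow]) -> None:
        vals = [raw[id(f)] for f in flows]
        lo, hi = min(vals), max(vals)
        for f in flows:
            t = 0.5 if hi == lo else (raw[id(f)] - lo) / (hi - lo)
            f.paint[overlay] = {
                "value": raw[id(f)],
                "normalized": t,
                "hex": _to_hex(cmap(t)),
            }

    if scale == "global":
        paint_group(g.flows)
    else:
        for j in range(len(g.columns) - 1):
            paint_group(g.flows_between(j))
    return overlay


def paint_flows_gep(
    g: SankeyGraph,
    expr: ExpressionMatrix,
    genes: GeneSet,
    overlay_name: str | None = None,
) -> str:
    """Paint every flow by its GEP triple mapped linearly to RGB."""
    genes.require_triple()
    genes.check_present(expr)
    overlay = overlay_name or "gep:" + "/".join(genes.genes)
    for f in g.flows:
        t = compute_gep(f, expr, genes)
        f.paint[overlay] = {
            "gep": list(t.fractions),
            "defined": t.defined,
            "hex": gep_to_hex(t),
        }
    return overlay


def ternary_dataset(
    g: SankeyGraph, expr: ExpressionMatrix, genes: GeneSet
) -> list[TernaryPoint]:
    """One ternary point per flow with a defined GEP, in flow order."""
    genes.require_triple()
    genes.check_present(expr)
    points = []
    for f in g.flows:
        t = compute_gep(f, expr, genes)
        if not t.defined:
            continue
        points.append(
            TernaryPoint(
                source=f.source,
                target=f.target,
                gep=t,
                count=f.count,
                size=POINT_SIZE_SCALAR * float(np.log2(f.count)),
                color=gep_to_hex(t),
            )
        )
    return points
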