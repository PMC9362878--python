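"""Per-cluster evaluation metrics, node painting support and marker tags.

Silhouette: for cell i with mean intra-cluster distance a(i) (self
excluded) and b(i) the smallest mean distance to any other cluster,
s(i) = (b - a) / max(a, b); s(i) = 0 for singleton clusters and when
a = b = 0.  The per-cluster value is the mean of s(i) over members, in
[-1, 1]; low values flag clusters whose members sit near a neighbouring
cluster's decision boundary.  Distances are Euclidean in the supplied
embedding, the same metric the kNN graph uses.

Normalization for node painting is affine (s + 1) / 2 by default (a
bijection of [-1, 1] onto [0, 1]); min-max over all nodes is available for
arbitrary ingested metrics.

Marker tags are one-vs-rest Wilcoxon rank-sum tests per gene (normal
approximation with tie correction), ranked by p-value, with
Benjamini-Hochberg FDR reported alongside.  The tags are descriptive
hover content, not a calibrated differential-expression analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

from .graph import ClusterNode, SankeyGraph
from .io import AnnotationTable, EmbeddingMatrix, ExpressionMatrix

_log = logging.getLogger("cellflows.metrics")

__all__ = [
    "ClusterMetricTable",
    "silhouette_per_cluster",
    "normalize_metric",
    "other_metrics",
    "top_de_genes",
    "annotate_graph_metrics",
    "ingest_annotations",
]

TOP_DE_DEFAULT_K = 5  # genes shown in the node-hover marker list


@dataclass
class ClusterMetricTable:
    """Rows keyed by node_id: one raw (and optionally normalized) value per
    node per metric."""

    metric: str
    raw: dict[str, float]
    normalized: dict[str, float] | None = None


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("cluster metrics require at least 2 clusters")
    return labels


def silhouette_per_cluster(
    emb: EmbeddingMatrix,
    labels: np.ndarray,
    resolution_name: str,
) -> ClusterMetricTable:
    """Mean silhouette per cluster for one assignment column.

    Returns a table keyed ``"<resolution>_<label>"``; raw values lie in
    [-1, 1].
    """
    labels = _check_labels(labels)
    if labels.shape[0] != emb.n_cells:
        raise ValueError("labels do not match embedding rows")
    s = silhouette_samples(emb.components, labels, metric="euclidean")
    raw = {}
    for lab in np.unique(labels):
        raw[f"{resolution_name}_{int(lab)}"] = float(s[labels == lab].mean())
    return ClusterMetricTable(metric="silhouette", raw=raw)


def normalize_metric(table: ClusterMetricTable, mode: str = "affine") -> ClusterMetricTable:
    """Attach normalized values in [0, 1].

    ``affine`` maps [-1, 1] linearly to [0, 1] ((s + 1) / 2; the default
    for silhouette).  ``minmax`` rescales over all rows; a constant input
    maps every node to 0.5.
    """
    if mode == "affine":
        norm = {k: (v + 1.0) / 2.0 for k, v in table.raw.items()}
    elif mode == "minmax":
        vals = list(table.raw.values())
        lo, hi = min(vals), max(vals)
        if hi == lo:
            norm = {k: 0.5 for k in table.raw}
        else:
            norm = {k: (v - lo) / (hi - lo) for k, v in table.raw.items()}
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ClusterMetricTable(metric=table.metric, raw=dict(table.raw), normalized=norm)


def other_metrics(
    emb: EmbeddingMatrix,
    labels: np.ndarray,
    resolution_name: str,
) -> list[ClusterMetricTable]:
    """Column-level Calinski-Harabasz and Davies-Bouldin scores.

    Both are properties of the whole partition, so the same value is
    attached to every node of the column.
    """
    labels = _check_labels(labels)
    ch = float(calinski_harabasz_score(emb.components, labels))
    db = float(davies_bouldin_score(emb.components, labels))
    keys = [f"{resolution_name}_{int(lab)}" for lab in np.unique(labels)]
    return [
        ClusterMetricTable(metric="calinski_harabasz", raw={k: ch for k in keys}),
        ClusterMetricTable(metric="davies_bouldin", raw={k: db for k in keys}),
    ]


def top_de_genes(
    expr: ExpressionMatrix,
    node_index: np.ndarray,
    rest_index: np.ndarray,
    k: int = TOP_DE_DEFAULT_K,
) -> pd.DataFrame:
    """Top-k one-vs-rest rank-sum marker genes for one cluster.

    Each gene is tested with the two-sided Wilcoxon rank-sum test (normal
    approximation, tie-corrected) of the cluster's cells against the rest
    of the same column.  Genes are ranked by ascending p-value, ties broken
    by descending mean difference (cluster minus rest), then gene id.

    Returns a DataFrame with columns ``gene``, ``p``, ``fdr``,
    ``mean_diff`` and ``direction`` ("up"/"down").
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    node_index = np.asarray(node_index)
    rest_index = np.asarray(rest_index)
    if node_index.size == 0:
        raise ValueError("empty cluster")
    if rest_index.size == 0:
        raise ValueError("one-vs-rest test needs a non-empty rest (single-cluster column?)")
    inside = expr.submatrix(node_index, expr.gene_ids)
    outside = expr.submatrix(rest_index, expr.gene_ids)
    # vectorized over genes: asymptotic MWU with tie correction
    res = mannwhitneyu(inside, outside, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.atleast_1d(res.pvalue)
    mean_diff = inside.mean(axis=0) - outside.mean(axis=0)
    fdr = false_discovery_control(pvals, method="bh")
    df = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "p": pvals,
            "fdr": fdr,
            "mean_diff": mean_diff,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        }
    )
    df = df.sort_values(
        ["p", "mean_diff", "gene"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(k)


# ---------------------------------------------------------------------------
# Attaching metrics and annotations to the graph
# ---------------------------------------------------------------------------


def annotate_graph_metrics(
    g: SankeyGraph,
    emb: EmbeddingMatrix,
    expr: ExpressionMatrix | None = None,
    top_k: int = TOP_DE_DEFAULT_K,
) -> None:
    """Compute silhouette (+ normalized), CH/DB and optional marker tags for
    every node and store them in the node annotation maps."""
    for j, col in enumerate(g.columns):
        labels = np.empty(g.n_cells, dtype=np.int64)
        for nd in col:
            labels[nd.member_index] = nd.label
        rname = g.resolution_names[j]
        if len(col) >= 2:
            sil = normalize_metric(
                silhouette_per_cluster(emb, labels, rname), mode="affine"
            )
            tables = [sil] + other_metrics(emb, labels, rname)
        else:
            tables = []
        for table in tables:
            for nd in col:
                nd.annotations[table.metric] = table.raw[nd.node_id]
                if table.normalized is not None:
                    nd.annotations[f"{table.metric}_normalized"] = table.normalized[nd.node_id]
        if expr is not None and len(col) >= 2:
            all_index = np.arange(g.n_cells)
            for nd in col:
                rest = np.setdiff1d(all_index, nd.member_index, assume_unique=True)
                tags = top_de_genes(expr, nd.member_index, rest, k=top_k)
                nd.annotations["top_genes"] = list(tags["gene"])


def ingest_annotations(
    g: SankeyGraph, table: AnnotationTable, strict: bool = True
) -> None:
    """Merge an externally computed per-cluster annotation table (e.g. GO
    term titles and enrichment scores) into the node annotation maps.

    Keys are (resolution name, cluster label).  In strict mode an
    unresolvable key is an error; in permissive mode the row is skipped
    and logged.
    """
    index = {nd.node_id: nd for nd in g.nodes}
    skipped = 0
    for rname, label, values in table.rows():
        nid = f"{rname}_{label}"
        nd = index.get(nid)
        if nd is None:
            if strict:
                raise ValueError(f"annotation key {nid!r} does not match any node")
            skipped += 1
            _log.warning("ingest_annotations: skipping unknown node %s", nid)
            continue
        nd.annotations.update(values)
    if skipped:
        _log.info("ingest_annotations: skipped %d of %d rows", skipped, len(table.table))
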