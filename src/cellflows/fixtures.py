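"""Planted hierarchical single-cell fixtures.

Generates everything the tool consumes — a normalized expression matrix, a
PCA embedding and a ground-truth multi-resolution assignment matrix — from
a planted hierarchy of cluster prototypes, so the full pipeline is
testable without any download.

The hierarchy is a tree.  Every internal node carries a *split
resolution*: below it the node's cells form one cluster, at and above it
they split into the node's children.  Cutting the tree at each grid
resolution therefore yields assignment columns that are successive
refinements — a coarser column's clusters always nest whole inside finer
ones — which makes the expected flow table exactly computable from the
tree and gives known ground-truth split points for stability tracing.

Expression is built from per-leaf prototypes: a shared non-negative
baseline plus elevated marker genes per leaf, under multiplicative
lognormal noise (negative values cannot arise, but the generator clips at
zero anyway for safety with user-supplied baselines).  This emulates
normalized (post-QC) expression, not raw counts: there is no dropout and
no library-size variation, which is sufficient for partition-recovery and
flow-accounting tests but says nothing about count-level preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .graph import size_rank_column
from .io import CellAssignmentMatrix, EmbeddingMatrix, ExpressionMatrix

_log = logging.getLogger("cellflows.fixtures")

__all__ = [
    "HierarchyNode",
    "PlantedHierarchy",
    "generate",
    "expected_flow_table",
    "pbmc_like_preset",
    "split_fixture_hierarchy",
]


@dataclass
class HierarchyNode:
    """A tree node: a leaf holds cells and markers; an internal node holds
    children plus the resolution at which it splits into them."""

    name: str
    n_cells: int = 0                       # leaves only
    markers: list[int] = field(default_factory=list)  # marker gene indices
    marker_level: float = 5.0              # prototype expression of markers
    split_resolution: float | None = None  # internal nodes only
    children: list["HierarchyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["HierarchyNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def total_cells(self) -> int:
        return sum(leaf.n_cells for leaf in self.leaves())


@dataclass
class PlantedHierarchy:
    """The generator configuration: tree + grid + noise + gene space."""

    root: HierarchyNode
    resolutions: np.ndarray
    n_genes: int
    baseline: float = 0.5     # shared prototype expression of non-markers
    noise_sigma: float = 0.4  # lognormal sigma of the multiplicative noise
    n_components: int = 10    # PCA dimensionality of the embedding

    def __post_init__(self) -> None:
        self.resolutions = np.asarray(self.resolutions, dtype=float)
        if self.resolutions.size < 2 or np.any(np.diff(self.resolutions) <= 0):
            raise ValueError("need a strictly increasing grid of >= 2 resolutions")
        lo, hi = self.resolutions[0], self.resolutions[-1]
        for node in _walk(self.root):
            if not node.is_leaf:
                if node.split_resolution is None:
                    raise ValueError(f"internal node {node.name} has no split resolution")
                if node is not self.root and not (lo <= node.split_resolution <= hi):
                    raise ValueError(
                        f"split resolution of {node.name} lies outside the grid"
                    )
            elif node.n_cells < 1:
                raise ValueError(f"leaf {node.name} has no cells")
        for leaf in self.root.leaves():
            if any(m >= self.n_genes for m in leaf.markers):
                raise ValueError("marker gene index outside the gene space")


def _walk(node: HierarchyNode):
    yield node
    for c in node.children:
        yield from _walk(c)


def _cut(node: HierarchyNode, resolution: float) -> list[HierarchyNode]:
    """Blocks of the partition at one resolution: maximal subtrees whose
    root has not yet split."""
    if node.is_leaf or node.split_resolution > resolution:
        return [node]
    return [b for c in node.children for b in _cut(c, resolution)]


def generate(
    h: PlantedHierarchy, seed: int = 0
) -> tuple[ExpressionMatrix, EmbeddingMatrix, CellAssignmentMatrix]:
    """Sample a fixture: expression, PCA embedding and ground-truth columns.

    Bit-identical under the same seed.  Ground-truth labels per column are
    size-ordered (label 0 = largest block), matching the convention of the
    rest of the pipeline.
    """
    rng = np.random.default_rng(seed)
    leaves = h.root.leaves()
    n = h.root.total_cells()
    cell_ids = [f"cell{i:05d}" for i in range(n)]
    gene_ids = [f"gene{j:03d}" for j in range(h.n_genes)]

    # leaf membership: contiguous blocks shuffled into a random cell order
    leaf_of = np.concatenate(
        [np.full(leaf.n_cells, li, dtype=np.int64) for li, leaf in enumerate(leaves)]
    )
    rng.shuffle(leaf_of)

    prototypes = np.full((len(leaves), h.n_genes), h.baseline)
    for li, leaf in enumerate(leaves):
        for m in leaf.markers:
            prototypes[li, m] = leaf.marker_level
    noise = rng.lognormal(mean=0.0, sigma=h.noise_sigma, size=(n, h.n_genes))
    values = np.clip(prototypes[leaf_of] * noise, 0.0, None)
    expr = ExpressionMatrix(cell_ids=cell_ids, gene_ids=gene_ids, values=values)

    d = min(h.n_components, h.n_genes, n)
    pca = PCA(n_components=d, svd_solver="full", random_state=0)
    emb = EmbeddingMatrix(cell_ids=cell_ids, components=pca.fit_transform(values))

    labels = np.empty((n, h.resolutions.size), dtype=np.int64)
    for j, res in enumerate(h.resolutions):
        blocks = _cut(h.root, res)
        block_sets = []
        for block in blocks:
            members = {id(leaf) for leaf in block.leaves()}
            block_sets.append(members)
        leaf_block = np.empty(len(leaves), dtype=np.int64)
        for li, leaf in enumerate(leaves):
            leaf_block[li] = next(
                b for b, s in enumerate(block_sets) if id(leaf) in s
            )
        col = leaf_block[leaf_of]
        labels[:, j], _ = size_rank_column(col)  # size-order the ground truth
    assign = CellAssignmentMatrix(
        cell_ids=cell_ids, resolutions=h.resolutions.copy(), labels=labels
    )
    return expr, emb, assign


def expected_flow_table(h: PlantedHierarchy) -> dict[int, list[tuple[frozenset, frozenset]]]:
    """Per column pair, the (source leaves, target leaves) block pairs the
    tree predicts a flow for.  A coarse block flows into exactly the blocks
    it refines into, so each pair shares the target block's full leaf set."""
    out: dict[int, list[tuple[frozenset, frozenset]]] = {}
    for j in range(h.resolutions.size - 1):
        src_blocks = _cut(h.root, h.resolutions[j])
        tgt_blocks = _cut(h.root, h.resolutions[j + 1])
        pairs = []
        for tb in tgt_blocks:
            tset = frozenset(leaf.name for leaf in tb.leaves())
            sb = next(
                b for b in src_blocks
                if tset <= frozenset(leaf.name for leaf in b.leaves())
            )
            pairs.append((frozenset(leaf.name for leaf in sb.leaves()), tset))
        out[j] = pairs
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def pbmc_like_preset() -> PlantedHierarchy:
    """A PBMC-shaped fixture: ~2700 cells, 8 leaf populations in a
    three-level hierarchy, resolution grid 0.1-0.5 in steps of 0.1.

    Genes 0, 1 and 2 are the designated co-expression markers: three of
    the major branches each elevate exactly one of them, so GEP triples of
    the branch-internal flows reach all three ternary corners.
    """
    lvl = dict(marker_level=6.0)
    #          root (splits immediately) -> 3 branches -> 8 leaves
    t_branch = HierarchyNode(
        name="T",
        split_resolution=0.3,
        children=[
            HierarchyNode(name="T.naive", n_cells=500, markers=[0, 10, 11], **lvl),
            HierarchyNode(
                name="T.cyto",
                split_resolution=0.5,
                children=[
                    HierarchyNode(name="T.cyto.a", n_cells=300, markers=[0, 12], **lvl),
                    HierarchyNode(name="T.cyto.b", n_cells=200, markers=[0, 13], **lvl),
                ],
            ),
        ],
    )
    b_branch = HierarchyNode(
        name="B",
        split_resolution=0.4,
        children=[
            HierarchyNode(name="B.naive", n_cells=400, markers=[1, 14, 15], **lvl),
            HierarchyNode(name="B.memory", n_cells=250, markers=[1, 16], **lvl),
        ],
    )
    m_branch = HierarchyNode(
        name="Myeloid",
        split_resolution=0.2,
        children=[
            HierarchyNode(name="Mono", n_cells=550, markers=[2, 17, 18], **lvl),
            HierarchyNode(
                name="DC.NK",
                split_resolution=0.4,
                children=[
                    HierarchyNode(name="DC", n_cells=300, markers=[2, 19], **lvl),
                    HierarchyNode(name="NK", n_cells=200, markers=[2, 20], **lvl),
                ],
            ),
        ],
    )
    root = HierarchyNode(
        name="root",
        split_resolution=0.1,
        children=[t_branch, b_branch, m_branch],
    )
    return PlantedHierarchy(
        root=root,
        resolutions=np.arange(1, 6) / 10.0,  # 0.1 .. 0.5
        n_genes=60,
        baseline=0.5,
        noise_sigma=0.4,
        n_components=10,
    )


def split_fixture_hierarchy(
    split_resolution: float = 0.3,
    n_persistent: int = 600,
    n_split: int = 600,
    n_genes: int = 30,
) -> PlantedHierarchy:
    """Two top-level clusters: one persists over the whole 0.1-0.5 grid,
    the other splits 50/50 at ``split_resolution``.  Used to verify that
    stable-path tracing recovers the planted split point exactly."""
    half = n_split // 2
    root = HierarchyNode(
        name="root",
        split_resolution=0.1,
        children=[
            HierarchyNode(name="stable", n_cells=n_persistent, markers=[0, 1], marker_level=6.0),
            HierarchyNode(
                name="splitter",
                split_resolution=split_resolution,
                children=[
                    HierarchyNode(name="split.a", n_cells=half, markers=[2, 3], marker_level=6.0),
                    HierarchyNode(name="split.b", n_cells=n_split - half, markers=[4, 5], marker_level=6.0),
                ],
            ),
        ],
    )
    return PlantedHierarchy(
        root=root, resolutions=np.arange(1, 6) / 10.0, n_genes=n_genes
    )
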