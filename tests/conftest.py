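import numpy as np
import pytest

import cellflows as cf


@pytest.fixture(scope="session")
def preset_data():
    """The PBMC-shaped planted fixture, generated once per session."""
    expr, emb, assign = cf.generate(cf.pbmc_like_preset(), seed=11)
    return expr, emb, assign


@pytest.fixture(scope="session")
def preset_graph(preset_data):
    _, _, assign = preset_data
    return cf.build_graph(assign)


@pytest.fixture()
def tiny_assign():
    """6 cells, 2 resolutions: one cluster splitting 3/3 plus a 2/4 imbalance."""
    labels = np.array(
        [[0, 0], [0, 0], [0, 1], [1, 2], [1, 2], [1, 2]], dtype=np.int64
    )
    return cf.CellAssignmentMatrix(
        cell_ids=[f"c{i}" for i in range(6)],
        resolutions=np.array([0.1, 0.2]),
        labels=labels,
    )


def random_assignment_matrix(rng, n_cells, n_res=5, max_clusters=8):
    """A random (valid) assignment matrix; labels compacted per column."""
    labels = np.empty((n_cells, n_res), dtype=np.int64)
    for j in range(n_res):
        k = rng.integers(2, max_clusters + 1)
        col = rng.integers(0, k, size=n_cells)
        _, col = np.unique(col, return_inverse=True)  # every label occupied
        labels[:, j] = col
    return cf.CellAssignmentMatrix(
        cell_ids=[f"c{i}" for i in range(n_cells)],
        resolutions=0.1 * np.arange(1, n_res + 1),
        labels=labels,
    )


def brute_force_flow_tally(assign, j):
    """Independent per-cell tally of flows between columns j and j+1."""
    tally = {}
    src, tgt = assign.column(j), assign.column(j + 1)
    for i in range(assign.n_cells):
        tally.setdefault((int(src[i]), int(tgt[i])), []).append(i)
    return tally
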