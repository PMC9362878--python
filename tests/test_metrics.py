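import numpy as np
import pytest

import cellflows as cf


def embedding(X):
    X = np.asarray(X, dtype=float)
    return cf.EmbeddingMatrix(cell_ids=[f"c{i}" for i in range(len(X))], components=X)


def brute_force_silhouette(X, labels):
    """Textbook O(n^2) per-cell silhouette, averaged per cluster."""
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():  # singleton cluster
            s[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return {int(lab): s[labels == lab].mean() for lab in np.unique(labels)}


class TestSilhouette:
    def test_far_separated_blobs_near_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(0.0, 0.5, size=(40, 3)),
            rng.normal(100.0, 0.5, size=(40, 3)),
        ])
        labels = np.repeat([0, 1], 40)
        table = cf.silhouette_per_cluster(embedding(X), labels, "0.1")
        assert table.raw["0.1_0"] >= 0.99
        assert table.raw["0.1_1"] >= 0.99

    def test_identical_coordinates_give_zero(self):
        X = np.zeros((10, 2))
        labels = np.repeat([0, 1], 5)
        table = cf.silhouette_per_cluster(embedding(X), labels, "0.1")
        assert table.raw["0.1_0"] == 0.0 and table.raw["0.1_1"] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="at least 2 clusters"):
            cf.silhouette_per_cluster(embedding(np.zeros((5, 2))), np.zeros(5), "0.1")

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(150, 4))
        labels = rng.integers(0, 4, size=150)
        table = cf.silhouette_per_cluster(embedding(X), labels, "0.2")
        expected = brute_force_silhouette(X, labels)
        for lab, val in expected.items():
            assert abs(table.raw[f"0.2_{lab}"] - val) < 1e-10

    def test_invariant_to_cell_and_label_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        base = cf.silhouette_per_cluster(embedding(X), labels, "0.1")
        perm = rng.permutation(60)
        relabel = np.array([2, 0, 1])  # label permutation
        moved = cf.silhouette_per_cluster(
            embedding(X[perm]), relabel[labels[perm]], "0.1"
        )
        for lab in range(3):
            assert moved.raw[f"0.1_{relabel[lab]}"] == pytest.approx(
                base.raw[f"0.1_{lab}"]
            )


class TestNormalizeMetric:
    def test_affine_endpoints(self):
        table = cf.ClusterMetricTable("silhouette", {"a": -1.0, "b": 1.0, "c": 0.0})
        out = cf.normalize_metric(table, mode="affine")
        assert out.normalized == {"a": 0.0, "b": 1.0, "c": 0.5}

    def test_minmax(self):
        table = cf.ClusterMetricTable("score", {"a": 0.2, "b": 0.6})
        out = cf.normalize_metric(table, mode="minmax")
        assert out.normalized == {"a": 0.0, "b": 1.0}

    def test_minmax_constant_input(self):
        table = cf.ClusterMetricTable("score", {"a": 7.0, "b": 7.0})
        out = cf.normalize_metric(table, mode="minmax")
        assert out.normalized == {"a": 0.5, "b": 0.5}


def brute_force_ch(X, labels):
    n = len(X)
    k = len(np.unique(labels))
    mean = X.mean(axis=0)
    between = sum(
        (labels == lab).sum() * np.sum((X[labels == lab].mean(axis=0) - mean) ** 2)
        for lab in np.unique(labels)
    )
    within = sum(
        np.sum((X[labels == lab] - X[labels == lab].mean(axis=0)) ** 2)
        for lab in np.unique(labels)
    )
    return (between / (k - 1)) / (within / (n - k))


def brute_force_db(X, labels):
    labs = np.unique(labels)
    cents = np.array([X[labels == lab].mean(axis=0) for lab in labs])
    spread = np.array([
        np.mean(np.linalg.norm(X[labels == lab] - cents[i], axis=1))
        for i, lab in enumerate(labs)
    ])
    total = 0.0
    for i in range(len(labs)):
        total += max(
            (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(labs))
            if j != i
        )
    return total / len(labs)


class TestOtherMetrics:
    def test_separated_beats_random_split(self):
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(50, 3)),
            rng.normal(30.0, 1.0, size=(50, 3)),
        ])
        good = np.repeat([0, 1], 50)
        bad = rng.integers(0, 2, size=100)
        ch_good = cf.other_metrics(embedding(X), good, "0.1")[0].raw["0.1_0"]
        ch_bad = cf.other_metrics(embedding(X), bad, "0.1")[0].raw["0.1_0"]
        assert ch_good > ch_bad

    def test_column_level_value_attached_to_every_node(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        for table in cf.other_metrics(embedding(X), labels, "0.3"):
            assert len(set(table.raw.values())) == 1
            assert set(table.raw) == {f"0.3_{k}" for k in range(3)}

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 4))
        labels = rng.integers(0, 3, size=100)
        ch_table, db_table = cf.other_metrics(embedding(X), labels, "0.1")
        assert ch_table.raw["0.1_0"] == pytest.approx(brute_force_ch(X, labels))
        assert db_table.raw["0.1_0"] == pytest.approx(brute_force_db(X, labels))


class TestTopDeGenes:
    def make_expr(self, values):
        values = np.asarray(values, dtype=float)
        return cf.ExpressionMatrix(
            cell_ids=[f"c{i}" for i in range(values.shape[0])],
            gene_ids=[f"g{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_perfectly_separating_gene_ranks_first(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(1.0, 1.0, size=(80, 10))
        values[:40, 3] += 50.0  # gene g3 exclusive to the node
        expr = self.make_expr(values)
        top = cf.top_de_genes(expr, np.arange(40), np.arange(40, 80), k=5)
        assert top.iloc[0]["gene"] == "g3"
        assert top.iloc[0]["direction"] == "up"
        assert len(top) == 5

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(1.0, 1.0, size=(40, 8))
        expr = self.make_expr(values)
        node, rest = np.arange(20), np.arange(20, 40)
        base = cf.top_de_genes(expr, node, rest, k=8)
        top2 = cf.top_de_genes(expr, rng.permutation(node), rng.permutation(rest), k=8)
        assert base["gene"].tolist() == top2["gene"].tolist()

    def test_statistic_matches_exhaustive_ranking(self):
        from scipy.stats import rankdata, norm

        rng = np.random.default_rng(6)
        values = rng.gamma(1.0, 1.0, size=(20, 1))
        expr = self.make_expr(values)
        node, rest = np.arange(8), np.arange(8, 20)
        top = cf.top_de_genes(expr, node, rest, k=1)
        # direct rank computation: normal approximation of the rank-sum test
        x, y = values[node, 0], values[rest, 0]
        ranks = rankdata(np.concatenate([x, y]))
        n1, n2 = len(x), len(y)
        U = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        # tie-corrected variance
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie = (counts**3 - counts).sum()
        n = n1 + n2
        sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1))))
        z = (U - mu - 0.5 * np.sign(U - mu)) / sigma  # continuity-corrected
        p = 2 * norm.sf(abs(z))
        assert top.iloc[0]["p"] == pytest.approx(p, rel=1e-10)

    def test_k_at_least_gene_count_returns_total_order(self):
        rng = np.random.default_rng(7)
        expr = self.make_expr(rng.gamma(1.0, 1.0, size=(30, 6)))
        top = cf.top_de_genes(expr, np.arange(15), np.arange(15, 30), k=100)
        assert len(top) == 6
        assert sorted(top["gene"]) == [f"g{j}" for j in range(6)]

    def test_empty_rest_rejected(self):
        expr = self.make_expr(np.ones((4, 2)))
        with pytest.raises(ValueError, match="rest"):
            cf.top_de_genes(expr, np.arange(4), np.array([], dtype=int), k=1)


class TestIngestAnnotations:
    def test_values_attach_to_nodes(self, tiny_assign):
        import pandas as pd

        g = cf.build_graph(tiny_assign)
        table = cf.AnnotationTable(pd.DataFrame(
            {"resolution": ["0.1"], "cluster": [0], "go_score": [42.0],
             "go_term": ["immune response"]}
        ))
        cf.ingest_annotations(g, table)
        node = g.node("0.1_0")
        assert node.annotations["go_score"] == 42.0
        assert node.annotations["go_term"] == "immune response"

    def test_strict_unknown_key_is_error(self, tiny_assign):
        import pandas as pd

        g = cf.build_graph(tiny_assign)
        table = cf.AnnotationTable(pd.DataFrame(
            {"resolution": ["0.1"], "cluster": [99], "score": [1.0]}
        ))
        with pytest.raises(ValueError, match="0.1_99"):
            cf.ingest_annotations(g, table, strict=True)

    def test_permissive_skips_and_logs_bad_rows(self, tiny_assign, caplog):
        import pandas as pd

        g = cf.build_graph(tiny_assign)
        rows = {"resolution": ["0.1"] * 9 + ["9.9"],
                "cluster": [0, 1] * 4 + [0, 0],
                "score": list(range(10))}
        table = cf.AnnotationTable(pd.DataFrame(rows))
        with caplog.at_level("INFO", logger="cellflows.metrics"):
            cf.ingest_annotations(g, table, strict=False)
        assert any("skipped 1 of 10" in r.message for r in caplog.records)


def test_annotate_graph_metrics_populates_nodes(preset_data, preset_graph):
    expr, emb, _ = preset_data
    cf.annotate_graph_metrics(preset_graph, emb, expr)
    for nd in preset_graph.nodes:
        assert "silhouette" in nd.annotations
        assert 0.0 <= nd.annotations["silhouette_normalized"] <= 1.0
        assert -1.0 <= nd.annotations["silhouette"] <= 1.0
        assert len(nd.annotations["top_genes"]) == 5
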