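import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import cellflows as cf
from cellflows.graph import Flow


def make_expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return cf.ExpressionMatrix(
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=genes,
        values=values,
    )


def make_flow(member_index, source="0.1_0", target="0.2_0", n_src=None, n_tgt=None):
    member_index = np.asarray(member_index)
    n = member_index.size
    return Flow(
        source=source,
        target=target,
        count=n,
        member_index=member_index,
        forward_prop=n / (n_src or n),
        backward_prop=n / (n_tgt or n),
    )


class TestFlowMeanExpression:
    def test_simple_mean(self):
        expr = make_expr([[1.0], [3.0], [99.0]])
        assert cf.flow_mean_expression(make_flow([0, 1]), expr, "g0") == 2.0

    def test_zero_gene(self):
        expr = make_expr([[0.0], [0.0]])
        assert cf.flow_mean_expression(make_flow([0, 1]), expr, "g0") == 0.0

    def test_unknown_gene_lists_near_matches(self):
        expr = make_expr([[1.0]], genes=["CD3E"])
        with pytest.raises(KeyError, match="CD3E"):
            cf.flow_mean_expression(make_flow([0]), expr, "cd3")

    def test_matches_brute_force_on_fixture(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        vec = expr.gene_vector("gene000")
        for f in preset_graph.flows[:6]:
            expected = sum(vec[i] for i in f.member_index) / f.count
            assert cf.flow_mean_expression(f, expr, "gene000") == pytest.approx(expected)


class TestComputeGep:
    def test_single_expressed_gene_hits_corner(self):
        expr = make_expr([[2.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        t = cf.compute_gep(make_flow([0, 1]), expr, cf.GeneSet(("g0", "g1", "g2")))
        assert t.defined and t.fractions == (1.0, 0.0, 0.0)

    def test_equal_expression_is_centroid(self):
        expr = make_expr([[1.0, 2.0, 0.0], [2.0, 1.0, 3.0]])
        t = cf.compute_gep(make_flow([0, 1]), expr, cf.GeneSet(("g0", "g1", "g2")))
        assert t.fractions == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_zero_denominator_undefined(self):
        expr = make_expr([[0.0, 0.0, 0.0]])
        t = cf.compute_gep(make_flow([0]), expr, cf.GeneSet(("g0", "g1", "g2")))
        assert not t.defined

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.gamma(1.0, 1.0, size=(80, 3))
        expr = make_expr(values)
        members = rng.choice(80, size=50, replace=False)
        t = cf.compute_gep(make_flow(members), expr, cf.GeneSet(("g0", "g1", "g2")))
        # brute-force double summation, cell by cell, gene by gene
        num = [0.0, 0.0, 0.0]
        den = 0.0
        for j in members:
            for i in range(3):
                num[i] += values[j, i]
                den += values[j, i]
        for i in range(3):
            assert abs(t.fractions[i] - num[i] / den) < 1e-12
        assert abs(sum(t.fractions) - 1.0) < 1e-9

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(1.0, 1.0, size=(30, 3))
        expr = make_expr(values)
        gs = cf.GeneSet(("g0", "g1", "g2"))
        a = cf.compute_gep(make_flow(np.arange(30)), expr, gs)
        b = cf.compute_gep(make_flow(rng.permutation(30)), expr, gs)
        assert a.fractions == pytest.approx(b.fractions)

    @settings(max_examples=30, deadline=None)
    @given(hst.integers(0, 10_000), hst.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, scale):
        """Scaling all genes by a common constant leaves the GEP unchanged."""
        rng = np.random.default_rng(seed)
        values = rng.gamma(1.0, 1.0, size=(20, 3))
        gs = cf.GeneSet(("g0", "g1", "g2"))
        flow = make_flow(np.arange(20))
        a = cf.compute_gep(make_flow(np.arange(20)), make_expr(values), gs)
        b = cf.compute_gep(flow, make_expr(values * scale), gs)
        assert a.fractions == pytest.approx(b.fractions, abs=1e-9)

    def test_wrong_geneset_size_rejected(self):
        expr = make_expr([[1.0, 1.0]])
        with pytest.raises(ValueError, match="3 genes"):
            cf.compute_gep(make_flow([0]), expr, cf.GeneSet(("g0", "g1")))


class TestGepToHex:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ((1.0, 0.0, 0.0), "#FF0000"),
            ((0.0, 1.0, 0.0), "#00FF00"),
            ((0.0, 0.0, 1.0), "#0000FF"),
            ((1 / 3, 1 / 3, 1 / 3), "#555555"),  # round(85.0) per channel
            ((0.5, 0.5, 0.0), "#808000"),  # 127.5 rounds away from zero -> 128
        ],
    )
    def test_channel_mapping(self, fractions, expected):
        t = cf.GEPTriple(fractions=fractions, defined=True)
        assert cf.gep_to_hex(t) == expected

    def test_undefined_maps_to_neutral(self):
        t = cf.GEPTriple(fractions=(0.0, 0.0, 0.0), defined=False)
        assert cf.gep_to_hex(t) == "#BEBEBE"


class TestPaintFlowsExpression:
    def test_endpoints_under_global_scale(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        name = cf.paint_flows_expression(preset_graph, expr, "gene000")
        norms = [f.paint[name]["normalized"] for f in preset_graph.flows]
        assert min(norms) == 0.0 and max(norms) == 1.0

    def test_constant_values_map_to_midpoint(self, tiny_assign):
        g = cf.build_graph(tiny_assign)
        expr = make_expr(np.ones((6, 1)), genes=["flat"])
        name = cf.paint_flows_expression(g, expr, "flat")
        assert all(f.paint[name]["normalized"] == 0.5 for f in g.flows)

    def test_raw_values_equal_flow_means(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        name = cf.paint_flows_expression(preset_graph, expr, "gene010")
        for f in preset_graph.flows:
            assert f.paint[name]["value"] == pytest.approx(
                cf.flow_mean_expression(f, expr, "gene010")
            )

    def test_unknown_colormap_rejected(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        with pytest.raises(ValueError, match="colormap"):
            cf.paint_flows_expression(preset_graph, expr, "gene000",
                                      colormap="definitely-not-a-colormap")


class TestTernaryDataset:
    def test_point_sizes_follow_log2_rule(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        gs = cf.GeneSet(("gene000", "gene001", "gene002"))
        points = cf.ternary_dataset(preset_graph, expr, gs)
        for p in points:
            assert p.size == pytest.approx(2.0 * np.log2(p.count))

    def test_single_cell_flow_has_size_zero(self):
        expr = make_expr([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        labels = np.array([[0, 0], [0, 1]])
        m = cf.CellAssignmentMatrix(
            cell_ids=["c0", "c1"], resolutions=np.array([0.1, 0.2]), labels=labels
        )
        g = cf.build_graph(m)
        points = cf.ternary_dataset(g, expr, cf.GeneSet(("g0", "g1", "g2")))
        assert all(p.size == 0.0 for p in points if p.count == 1)
        assert len(points) == 2

    def test_one_point_per_defined_flow(self, preset_data, preset_graph):
        expr, _, _ = preset_data
        gs = cf.GeneSet(("gene000", "gene001", "gene002"))
        points = cf.ternary_dataset(preset_graph, expr, gs)
        defined = sum(
            cf.compute_gep(f, expr, gs).defined for f in preset_graph.flows
        )
        assert len(points) == defined

    def test_preset_markers_span_all_corners(self, preset_data, preset_graph):
        """The designated markers dominate one branch each, so some flow's
        GEP is close to each of the three ternary corners."""
        expr, _, _ = preset_data
        gs = cf.GeneSet(("gene000", "gene001", "gene002"))
        points = cf.ternary_dataset(preset_graph, expr, gs)
        arr = np.array([p.gep.fractions for p in points])
        for channel in range(3):
            assert arr[:, channel].max() > 0.7
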