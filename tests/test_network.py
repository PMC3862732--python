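"""Relevance network, ARACNE DPI, FDR retention, enrichment, components."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import bh_selected, mann_whitney_enum, triangle_eliminate
from marrownet.data_io import AnnotationMap
from marrownet.network import (
    RelevanceNetwork,
    aracne_prune,
    build_relevance_network,
    component_summary,
    connected_components,
    edge_class,
    edge_pdf,
    enrichment_test,
    fdr_pvalue_cutoff,
    fdr_retain,
    mi_from_correlation,
)
from marrownet.panels import AMINO, LIPID, OTHER


def _net_with_edges(edge_list):
    """edge_list: (u, v, mi) or (u, v, mi, p) tuples."""
    net = RelevanceNetwork()
    for entry in edge_list:
        u, v, mi = entry[:3]
        p = entry[3] if len(entry) > 3 else 0.01
        net.graph.add_edge(
            u, v, r=0.9, mi=mi, p=p, q=p, sign="correlated", edge_class="other"
        )
    return net


def _random_mi_graph(rng, n_nodes=8, edge_prob=0.5):
    nodes = [f"n{i}" for i in range(n_nodes)]
    mi = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                mi[frozenset((nodes[i], nodes[j]))] = float(rng.random())
    net = _net_with_edges([(tuple(sorted(e))[0], tuple(sorted(e))[1], v) for e, v in mi.items()])
    for node in nodes:
        net.graph.add_node(node)
    return net, nodes, mi


class TestMutualInformation:
    def test_zero_correlation_zero_information(self):
        assert mi_from_correlation(0.0) == 0.0

    def test_high_precision_value(self):
        assert mi_from_correlation(0.9) == pytest.approx(-0.5 * math.log(0.19), rel=1e-12)
        assert mi_from_correlation(0.9) == pytest.approx(0.830366, abs=1e-6)

    def test_even_and_increasing(self, rng):
        rs = rng.uniform(-0.999, 0.999, 50)
        for r in rs:
            assert mi_from_correlation(-r) == mi_from_correlation(r)
        mags = np.sort(np.abs(rs))
        values = [mi_from_correlation(r) for r in mags]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_clamps_at_unity(self):
        assert np.isfinite(mi_from_correlation(1.0))
        assert mi_from_correlation(1.0) == mi_from_correlation(-1.0)


class TestFdrCutoff:
    def test_worked_stepup_example(self):
        assert fdr_pvalue_cutoff([0.01, 0.02, 0.3, 0.6], 0.5) == pytest.approx(0.3)

    def test_all_ones_none(self):
        assert fdr_pvalue_cutoff([1.0, 1.0, 1.0], 0.5) is None

    def test_empty_none(self):
        assert fdr_pvalue_cutoff([], 0.5) is None

    def test_matches_bruteforce_selection(self, rng):
        from _oracles import bh_cutoff

        for _ in range(200):
            p = rng.random(rng.integers(1, 20)) ** 2
            assert fdr_pvalue_cutoff(p, 0.5) == bh_cutoff(p, 0.5)


class TestEdgeClass:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (LIPID, LIPID, "lipid"),
            (AMINO, AMINO, "amino"),
            (LIPID, AMINO, "other"),
            (LIPID, OTHER, "other"),
            (OTHER, OTHER, "other"),
        ],
    )
    def test_both_endpoints_rule(self, a, b, expected):
        assert edge_class(a, b) == expected


class TestBuildRelevanceNetwork:
    def _annotation(self, names):
        return AnnotationMap({n: OTHER for n in names})

    def test_collinear_pair_yields_single_edge(self, rng):
        n = 10
        base = rng.lognormal(1, 0.4, n)
        frame = pd.DataFrame(
            {"a": base, "b": base * 3.0, "c": rng.lognormal(1, 0.4, n)}
        )
        net = build_relevance_network(frame, self._annotation("abc"), fdr_admit=0.5)
        assert net.n_edges == 1
        assert net.graph.has_edge("a", "b")

    def test_sparse_metabolite_excluded(self, rng):
        col = rng.lognormal(1, 0.3, 10)
        sparse = col.copy()
        sparse[:6] = np.nan  # 4 nonzero values
        frame = pd.DataFrame(
            {"dense1": col, "dense2": rng.lognormal(1, 0.3, 10), "sparse": sparse}
        )
        net = build_relevance_network(frame, self._annotation(frame.columns))
        assert "sparse" not in net.graph.nodes

    def test_zero_values_do_not_count_as_detected(self, rng):
        col = rng.lognormal(1, 0.3, 10)
        zeros = col.copy()
        zeros[:6] = 0.0
        frame = pd.DataFrame(
            {"dense1": col, "dense2": rng.lognormal(1, 0.3, 10), "zeros": zeros}
        )
        net = build_relevance_network(frame, self._annotation(frame.columns))
        assert "zeros" not in net.graph.nodes

    def test_stricter_admission_is_subset(self, rng):
        frame = pd.DataFrame(
            rng.lognormal(1, 0.4, (10, 8)), columns=[f"m{i}" for i in range(8)]
        )
        loose = build_relevance_network(frame, self._annotation(frame.columns), fdr_admit=0.5)
        strict = build_relevance_network(frame, self._annotation(frame.columns), fdr_admit=0.1)
        assert set(strict.graph.edges()) <= set(loose.graph.edges())

    def test_edge_sign_tracks_correlation(self, rng):
        n = 12
        base = rng.lognormal(1, 0.4, n)
        frame = pd.DataFrame({"up": base, "down": base.max() * 1.5 - base,
                              "twin": base * 2})
        net = build_relevance_network(frame, self._annotation(frame.columns))
        for u, v, attrs in net.graph.edges(data=True):
            assert attrs["sign"] == ("anticorrelated" if attrs["r"] < 0 else "correlated")

    def test_admission_matches_bruteforce_bh(self, rng):
        frame = pd.DataFrame(
            rng.lognormal(1, 0.5, (10, 7)), columns=[f"m{i}" for i in range(7)]
        )
        from marrownet.correlation import pair_correlation

        net = build_relevance_network(frame, self._annotation(frame.columns), fdr_admit=0.5)
        names = list(frame.columns)
        candidates = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                _, p, _ = pair_correlation(frame[a], frame[b])
                candidates.append(((a, b), p))
        selected = bh_selected([p for _, p in candidates], 0.5)
        expected = {candidates[i][0] for i in selected}
        got = {tuple(sorted(e)) for e in net.graph.edges()}
        assert got == expected


class TestEdgePdf:
    def test_single_edge_reflected_kernel(self):
        net = _net_with_edges([("a", "b", 0.8, 0.02)])
        pdf = edge_pdf(net, "other", bandwidth=0.005)
        assert pdf.integral() == pytest.approx(1.0, abs=1e-3)
        peak = pdf.grid[np.argmax(pdf.density)]
        assert abs(peak - 0.02) < 0.005

    def test_integral_one_on_random_networks(self, rng):
        for _ in range(10):
            ps = rng.random(rng.integers(2, 30)) * 0.2
            net = _net_with_edges(
                [(f"a{i}", f"b{i}", 0.5, p) for i, p in enumerate(ps)]
            )
            pdf = edge_pdf(net, "other")
            assert pdf.integral() == pytest.approx(1.0, abs=1e-3)
            assert (pdf.density >= 0).all()

    def test_mass_concentrates_at_small_p(self):
        net = _net_with_edges([(f"a{i}", f"b{i}", 0.5, 0.001) for i in range(10)])
        pdf = edge_pdf(net, "other")
        assert pdf.density[0] == pdf.density.max()

    def test_missing_class_rejected(self):
        net = _net_with_edges([("a", "b", 0.5, 0.02)])
        with pytest.raises(ValueError):
            edge_pdf(net, "lipid")


class TestEnrichment:
    def _two_class_net(self, lipid_ps, other_ps):
        net = RelevanceNetwork()
        for i, p in enumerate(lipid_ps):
            net.graph.add_edge(f"l{i}", f"L{i}", r=0.9, mi=0.8, p=p, q=p,
                               sign="correlated", edge_class="lipid")
        for i, p in enumerate(other_ps):
            net.graph.add_edge(f"o{i}", f"O{i}", r=0.5, mi=0.2, p=p, q=p,
                               sign="correlated", edge_class="other")
        return net

    def test_exact_enumeration_example(self):
        net = self._two_class_net([0.001, 0.002, 0.003], [0.5, 0.6])
        res = enrichment_test(net, "lipid")
        assert res.p == pytest.approx(0.1)  # 1/C(5,3)
        assert res.direction == "lipid"

    def test_single_edge_each_side(self):
        net = self._two_class_net([0.01], [0.5])
        assert enrichment_test(net, "lipid").p == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            lipid = rng.random(rng.integers(1, 5)).tolist()
            other = rng.random(rng.integers(1, 5)).tolist()
            net = self._two_class_net(lipid, other)
            res = enrichment_test(net, "lipid")
            assert res.p == pytest.approx(
                mann_whitney_enum(lipid, other, "less"), abs=1e-12
            )

    def test_cross_network_uses_candidate_families(self):
        a = self._two_class_net([0.001, 0.002], [0.5])
        b = self._two_class_net([0.01], [0.5])
        a.candidate_p = {"lipid": np.array([0.001, 0.002, 0.003])}
        b.candidate_p = {"lipid": np.array([0.4, 0.5, 0.6])}
        res = enrichment_test(a, "lipid", versus="same_class_other_network", other=b)
        assert res.n_group == 3 and res.n_other == 3
        assert res.p == pytest.approx(mann_whitney_enum(
            [0.001, 0.002, 0.003], [0.4, 0.5, 0.6], "two-sided"), abs=1e-12)

    def test_empty_group_rejected(self):
        net = self._two_class_net([], [0.5])
        with pytest.raises(ValueError):
            enrichment_test(net, "lipid")


class TestAracne:
    def test_hand_triangle(self):
        net = _net_with_edges([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.5)])
        pruned = aracne_prune(net)
        assert set(map(frozenset, pruned.graph.edges())) == {
            frozenset(("a", "b")), frozenset(("b", "c")),
        }

    def test_open_path_untouched(self):
        net = _net_with_edges([("a", "b", 0.9), ("b", "c", 0.2)])
        pruned = aracne_prune(net)
        assert pruned.n_edges == 2

    def test_tied_minimum_removes_both(self):
        net = _net_with_edges([("a", "b", 0.9), ("b", "c", 0.5), ("a", "c", 0.5)])
        pruned = aracne_prune(net)
        assert set(map(frozenset, pruned.graph.edges())) == {frozenset(("a", "b"))}

    def test_mark_then_sweep_not_sequential(self):
        # triangles abc (min bc) and bcd (min bd) share edge bc; removing bc
        # first would dissolve bcd and spare bd, so simultaneous marking must
        # evaluate both triangles on the original graph and drop bd too
        net = _net_with_edges(
            [("a", "b", 0.9), ("a", "c", 0.8), ("b", "c", 0.5),
             ("b", "d", 0.4), ("c", "d", 0.45)]
        )
        pruned = aracne_prune(net)
        got = set(map(frozenset, pruned.graph.edges()))
        assert got == {frozenset(("a", "b")), frozenset(("a", "c")),
                       frozenset(("c", "d"))}

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            net, nodes, mi = _random_mi_graph(rng)
            pruned = aracne_prune(net)
            expected = triangle_eliminate(nodes, mi)
            got = {frozenset(e) for e in pruned.graph.edges()}
            assert got == expected

    def test_triangle_free_at_zero_tolerance(self, rng):
        for _ in range(50):
            net, _, _ = _random_mi_graph(rng, edge_prob=0.8)
            pruned = aracne_prune(net)
            assert sum(nx.triangles(pruned.graph).values()) == 0

    def test_positive_tolerance_spares_near_ties(self):
        net = _net_with_edges([("a", "b", 0.9), ("b", "c", 0.52), ("a", "c", 0.5)])
        pruned = aracne_prune(net, dpi_tolerance=0.05)
        assert pruned.n_edges == 3


class TestFdrRetain:
    def test_all_tiny_all_kept(self):
        net = _net_with_edges([(f"a{i}", f"b{i}", 0.5, 1e-9) for i in range(5)])
        assert fdr_retain(net, 0.01).n_edges == 5

    def test_all_half_none_kept(self):
        net = _net_with_edges([(f"a{i}", f"b{i}", 0.5, 0.5) for i in range(5)])
        assert fdr_retain(net, 0.01).n_edges == 0

    def test_matches_bruteforce_bh_selection(self, rng):
        for _ in range(50):
            ps = (rng.random(10) ** 3).tolist()
            net = _net_with_edges(
                [(f"a{i}", f"b{i}", 0.5, p) for i, p in enumerate(ps)]
            )
            kept = fdr_retain(net, 0.05)
            expected = bh_selected(ps, 0.05)
            got = {int(u[1:]) for u, v in kept.graph.edges()}
            assert got == expected

    def test_invert_flips_selection(self):
        ps = [1e-9, 1e-9, 0.9]
        net = _net_with_edges([(f"a{i}", f"b{i}", 0.5, p) for i, p in enumerate(ps)])
        assert fdr_retain(net, 0.01).n_edges == 2
        assert fdr_retain(net, 0.01, invert=True).n_edges == 1


class TestComponents:
    def test_edgeless_network_empty_list(self):
        net = RelevanceNetwork()
        net.graph.add_nodes_from("abcd")
        assert connected_components(net) == []

    def test_path_component_found_pair_ignored(self):
        net = _net_with_edges(
            [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("x", "y", 0.5)]
        )
        comps = connected_components(net, min_nodes=4)
        assert len(comps) == 1
        assert set(comps[0].graph.nodes()) == {"a", "b", "c", "d"}

    def test_component_edges_subset_of_input(self, rng):
        net, _, _ = _random_mi_graph(rng, n_nodes=10, edge_prob=0.3)
        all_edges = {frozenset(e) for e in net.graph.edges()}
        for comp in connected_components(net, min_nodes=2):
            assert {frozenset(e) for e in comp.graph.edges()} <= all_edges

    def test_ordering_by_size(self):
        net = _net_with_edges(
            [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("d", "e", 0.5),
             ("p", "q", 0.5), ("q", "r", 0.5), ("r", "s", 0.5)]
        )
        comps = connected_components(net, min_nodes=4)
        assert [c.n_nodes for c in comps] == [5, 4]


class TestComponentSummary:
    def test_single_edge_means(self):
        net = _net_with_edges([("a", "b", 0.830, 0.001)])
        summary = component_summary(net)
        assert summary.n_nodes == 2 and summary.n_edges == 1
        assert summary.mean_r2 == pytest.approx(0.81)
        assert summary.mean_p == pytest.approx(0.001)
        assert summary.mean_mi == pytest.approx(0.830)

    def test_two_edge_mean_r2(self):
        net = RelevanceNetwork()
        for i, r in enumerate((0.8, 0.6)):
            net.graph.add_edge(f"a{i}", f"b{i}", r=r, mi=0.5, p=0.01, q=0.01,
                               sign="correlated", edge_class="other")
        assert component_summary(net).mean_r2 == pytest.approx(0.5)

    def test_edgeless_rejected(self):
        net = RelevanceNetwork()
        net.graph.add_node("a")
        with pytest.raises(ValueError):
            component_summary(net)
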