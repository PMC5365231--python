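import pytest

from pathrank import (
    CostConfig,
    EndpointError,
    Network,
    PathQuery,
    astar_shortest_path,
    compute_subnetwork,
    enumerate_costed_paths,
    path_score,
    prepare_query_graph,
    reconstruct_pathways,
    reverse_dijkstra,
    validate_endpoints,
)


class TestPathQuery:
    def test_defaults(self):
        q = PathQuery(sources=["a"], targets=["b"])
        assert q.k == 200
        assert not q.allow_sources_targets_in_paths

    @pytest.mark.parametrize("bad", [-5, 0, "many", 2.5, None])
    def test_invalid_k_falls_back_to_default(self, bad, caplog):
        assert PathQuery(sources=["a"], targets=["b"], k=bad).k == 200
        assert "default" in caplog.text

    def test_targets_are_sources_copies_and_forces_allow(self):
        q = PathQuery(sources=["a", "b"], targets_are_sources=True)
        assert q.targets == ["a", "b"]
        assert q.allow_sources_targets_in_paths

    def test_endpoint_lists_deduplicated_in_order(self):
        q = PathQuery(sources=["b", "a", "b"], targets=["t"])
        assert q.sources == ["b", "a"]


class TestValidateEndpoints:
    def test_all_present_passes_unchanged(self, probability_net):
        s, t, warnings = validate_endpoints(probability_net, ["s"], ["t"])
        assert (s, t, warnings) == (["s"], ["t"], [])

    def test_absent_endpoint_skipped_with_warning(self, probability_net):
        s, _, warnings = validate_endpoints(probability_net, ["s", "zzz"], ["t"])
        assert s == ["s"]
        assert len(warnings) == 1 and "zzz" in warnings[0]

    def test_no_surviving_source_is_fatal(self, probability_net):
        with pytest.raises(EndpointError):
            validate_endpoints(probability_net, ["zzz"], ["t"])

    def test_no_surviving_target_is_fatal(self, probability_net):
        with pytest.raises(EndpointError):
            validate_endpoints(probability_net, ["s"], ["zzz"])

    def test_strict_mode_aborts_on_any_absence(self, probability_net):
        with pytest.raises(EndpointError):
            validate_endpoints(probability_net, ["s", "zzz"], ["t"], strict=True)


class TestPrepareQueryGraph:
    def test_super_nodes_and_zero_cost_edges(self, probability_net):
        q = PathQuery(sources=["s"], targets=["t"])
        graph, s_star, t_star = prepare_query_graph(probability_net, q, CostConfig("probability"))
        assert graph.n_nodes == probability_net.n_nodes + 2
        assert graph.cost(s_star, "s") == 0.0
        assert graph.cost("t", t_star) == 0.0

    def test_source_in_edges_removed_by_default(self):
        net = Network({"x", "a", "t"}, {("x", "a"): None, ("a", "t"): None})
        q = PathQuery(sources=["a"], targets=["t"])
        graph, _, _ = prepare_query_graph(net, q, CostConfig())
        assert dict(graph.out_edges("x")) == {}

    def test_allow_option_keeps_endpoint_edges(self):
        net = Network({"x", "a", "t"}, {("x", "a"): None, ("a", "t"): None})
        q = PathQuery(sources=["a"], targets=["t"], allow_sources_targets_in_paths=True)
        graph, _, _ = prepare_query_graph(net, q, CostConfig())
        assert dict(graph.out_edges("x")) == {"a": 1.0}

    def test_super_names_never_collide_with_network_nodes(self):
        net = Network({"<SOURCE>", "<TARGET>", "t"}, {("<SOURCE>", "t"): None})
        q = PathQuery(sources=["<SOURCE>"], targets=["t"])
        graph, s_star, t_star = prepare_query_graph(net, q, CostConfig())
        assert s_star not in net.nodes and t_star not in net.nodes


class TestReconstructPathways:
    def test_unweighted_diamond_scores_are_edge_counts(self, diamond_unweighted):
        q = PathQuery(sources=["s"], targets=["t"], k=10)
        res = reconstruct_pathways(diamond_unweighted, q, CostConfig())
        assert [(p.nodes, p.score) for p in res.paths] == [
            (("s", "a", "t"), 2),
            (("s", "b", "t"), 2),
        ]

    def test_probability_scores_appear_in_decreasing_order(self, probability_net):
        q = PathQuery(sources=["s"], targets=["t"], k=10)
        res = reconstruct_pathways(probability_net, q, CostConfig("probability"))
        scores = [p.score for p in res.paths]
        assert len(scores) >= 3
        assert scores == sorted(scores, reverse=True)

    def test_five_path_toy_annotates_first_path_indices(self):
        # two receptors feeding two TFs through a shared hub, five paths total
        net = Network(
            {"r1", "r2", "h", "m", "f1", "f2"},
            {
                ("r1", "h"): 0.9, ("r2", "h"): 0.8, ("h", "f1"): 0.9,
                ("h", "f2"): 0.7, ("r1", "m"): 0.5, ("m", "f2"): 0.5,
            },
        )
        q = PathQuery(sources=["r1", "r2"], targets=["f1", "f2"], k=5)
        res = reconstruct_pathways(net, q, CostConfig("probability"))
        assert len(res.paths) == 5
        for p in res.paths:
            assert p.nodes[0] in ("r1", "r2") and p.nodes[-1] in ("f1", "f2")
        first_rank_nodes = set(res.paths[0].nodes)
        for node in first_rank_nodes:
            assert res.subnetwork.node_index[node] == 1

    def test_single_self_connected_node_yields_no_paths(self):
        net = Network({"a", "b"}, {("a", "b"): None, ("b", "a"): None})
        q = PathQuery(sources=["a"], targets_are_sources=True)
        res = reconstruct_pathways(net, q, CostConfig())
        assert res.paths == []

    def test_targets_are_sources_pair_uses_only_real_edge(self):
        net = Network({"a", "b"}, {("a", "b"): 0.5})
        q = PathQuery(sources=["a", "b"], targets_are_sources=True)
        res = reconstruct_pathways(net, q, CostConfig("probability"))
        assert [(p.nodes, p.score) for p in res.paths] == [(("a", "b"), 0.5)]

    def test_sources_never_interior_under_default_exclusion(self):
        net = Network(
            {"s", "m", "x", "t"},
            {("s", "m"): None, ("m", "t"): None, ("s", "x"): None, ("x", "t"): None},
        )
        q = PathQuery(sources=["s", "m"], targets=["t"], k=20)
        res = reconstruct_pathways(net, q, CostConfig())
        for p in res.paths:
            assert not any(n in ("s", "m") for n in p.nodes[1:-1])
            assert "t" not in p.nodes[:-1]

    def test_allow_option_lets_a_source_sit_interior(self):
        net = Network({"s", "m", "t"}, {("s", "m"): None, ("m", "t"): None})
        q = PathQuery(sources=["s", "m"], targets=["t"], k=20,
                      allow_sources_targets_in_paths=True)
        res = reconstruct_pathways(net, q, CostConfig())
        assert ("s", "m", "t") in {p.nodes for p in res.paths}

    def test_scores_recompute_exactly(self, probability_net):
        q = PathQuery(sources=["s"], targets=["t"], k=10)
        cfg = CostConfig("probability")
        res = reconstruct_pathways(probability_net, q, cfg)
        for p in res.paths:
            assert p.score == path_score(p.nodes, probability_net, cfg)

    def test_rank1_cost_is_min_over_endpoint_pairs(self, probability_net):
        """Multi-endpoint correctness against the brute-force oracle."""
        cfg = CostConfig("probability")
        q = PathQuery(sources=["s", "a"], targets=["c", "t"], k=1)
        res = reconstruct_pathways(probability_net, q, cfg)
        graph, _, _ = prepare_query_graph(probability_net, q, cfg)
        best = min(
            cost
            for src in q.sources
            for tgt in q.targets
            for _, cost in enumerate_costed_paths(graph, src, tgt)
        )
        assert res.paths[0].internal_cost == best

    def test_missing_endpoints_warned_and_skipped(self, probability_net):
        q = PathQuery(sources=["s", "nope"], targets=["t"], k=5)
        res = reconstruct_pathways(probability_net, q, CostConfig("probability"))
        assert res.warnings and "nope" in res.warnings[0]
        assert res.paths

    def test_empty_network_is_fatal(self):
        with pytest.raises(EndpointError):
            reconstruct_pathways(Network(), PathQuery(sources=["a"], targets=["b"]))


class TestComputeSubnetwork:
    def test_single_path_all_indices_one(self, probability_net):
        from pathrank import RankedPath

        sub = compute_subnetwork(
            [RankedPath(rank=1, nodes=("s", "a", "t"), internal_cost=0.0)], probability_net
        )
        assert set(sub.node_index.values()) == {1}
        assert set(sub.edge_index.values()) == {1}
        assert sub.edge_weight[("s", "a")] == 0.9

    def test_later_path_elements_get_their_first_rank(self, probability_net):
        from pathrank import RankedPath

        sub = compute_subnetwork(
            [
                RankedPath(rank=1, nodes=("s", "a", "t"), internal_cost=0.0),
                RankedPath(rank=2, nodes=("s", "b", "t"), internal_cost=0.0),
            ],
            probability_net,
        )
        assert sub.node_index == {"s": 1, "a": 1, "t": 1, "b": 2}
        assert sub.edge_index[("s", "b")] == 2 and sub.edge_index[("s", "a")] == 1

    def test_empty_path_list_gives_empty_subnetwork(self, probability_net):
        sub = compute_subnetwork([], probability_net)
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_foreign_edge_is_contract_violation(self, probability_net):
        from pathrank import RankedPath

        with pytest.raises(KeyError):
            compute_subnetwork(
                [RankedPath(rank=1, nodes=("t", "s"), internal_cost=0.0)], probability_net
            )

    def test_subnetwork_is_exactly_the_union_of_paths(self, probability_net):
        q = PathQuery(sources=["s"], targets=["t"], k=10)
        res = reconstruct_pathways(probability_net, q, CostConfig("probability"))
        nodes = set()
        edges = set()
        for p in res.paths:
            nodes.update(p.nodes)
            edges.update(zip(p.nodes, p.nodes[1:]))
        assert set(res.subnetwork.node_index) == nodes
        assert set(res.subnetwork.edge_index) == edges
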