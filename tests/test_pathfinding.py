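"""Typed shortest-path search: classification, minimality, direction handling."""

import numpy as np
import pytest

from conftest import (
    brute_force_path_set,
    build_network,
    edge,
    engine_path_set,
    random_typed_network,
)
from masterpath.interactome import EdgeRecord, merge_networks
from masterpath.pathfinding import (
    LinearPath,
    classify_path_type,
    collect_shortest_path_set,
    extract_subnetwork,
    find_shortest_typed_paths,
)


class TestClassify:
    @pytest.mark.parametrize(
        "types, expected",
        [
            (["ppi", "ppi", "ppi"], "protein_protein"),
            (["ppi", "transcriptional", "ppi"], "transcriptional"),
            (["ppi", "mirna_mrna"], "mirna"),
            (["mirna_mrna", "transcriptional", "enzymatic"], "metabolic"),
            (["enzymatic"], "metabolic"),
        ],
    )
    def test_hierarchy(self, types, expected):
        assert classify_path_type(types) == expected

    def test_empty_sequence_fatal(self):
        with pytest.raises(ValueError):
            classify_path_type([])

    def test_unknown_type_fatal(self):
        with pytest.raises(ValueError):
            classify_path_type(["phosphorylation"])


class TestFindShortestTypedPaths:
    def test_undirected_diamond_two_paths(self):
        net = build_network([edge("h", "a"), edge("a", "f"), edge("h", "b"), edge("b", "f")])
        paths = find_shortest_typed_paths(net, "H", "F", 5)
        assert len(paths) == 2
        assert all(p.length == 2 and p.type_class == "protein_protein" for p in paths)

    def test_direct_transcriptional_edge(self):
        net = build_network([edge("h", "f", directed=True, itype="transcriptional")])
        paths = find_shortest_typed_paths(net, "H", "F", 5)
        assert len(paths) == 1
        assert paths[0].type_class == "transcriptional"
        assert paths[0].length == 1

    def test_direction_blocks_traversal(self):
        net = build_network([edge("f", "h", directed=True)])
        assert find_shortest_typed_paths(net, "H", "F", 5) == []

    def test_absent_endpoint_warns_and_skips(self, caplog):
        net = build_network([edge("a", "b")])
        assert find_shortest_typed_paths(net, "A", "ZZ", 3) == []
        assert "skipping pair" in caplog.text

    def test_identical_endpoints_rejected(self):
        net = build_network([edge("a", "b")])
        with pytest.raises(ValueError):
            find_shortest_typed_paths(net, "A", "A", 3)

    def test_per_class_minima_are_independent(self):
        # a 1-edge transcriptional route must not suppress a longer pure-PPI route
        net = build_network([
            edge("h", "f", directed=True, itype="transcriptional"),
            edge("h", "m"), edge("m", "f"),
        ])
        paths = find_shortest_typed_paths(net, "H", "F", 5)
        by_class = {p.type_class: p for p in paths}
        assert by_class["transcriptional"].length == 1
        assert by_class["protein_protein"].length == 2

    def test_lmax_excludes_long_class_minima(self):
        net = build_network([edge("h", "a"), edge("a", "b"), edge("b", "f")])
        assert find_shortest_typed_paths(net, "H", "F", 2) == []
        assert len(find_shortest_typed_paths(net, "H", "F", 3)) == 1

    def test_parallel_typed_edges_give_distinct_paths(self):
        net = merge_networks([[
            EdgeRecord("H", "F", True, "ppi", "x"),
            EdgeRecord("H", "F", True, "transcriptional", "x"),
        ]])
        paths = find_shortest_typed_paths(net, "H", "F", 3)
        assert {p.type_class for p in paths} == {"protein_protein", "transcriptional"}


class TestCollect:
    def test_single_shared_node_yields_empty_set(self):
        net = build_network([edge("x", "y")])
        ps = collect_shortest_path_set(net, ["X"], ["X"], 3)
        assert len(ps) == 0

    def test_toy10_has_seven_paths(self, toy):
        net, hits, impls = toy
        ps = collect_shortest_path_set(net, hits, impls, 5)
        assert len(ps) == 7
        assert [(p.anchor, p.length) for p in ps.paths] == [
            (("TB", "TA"), 3), (("TB", "TA"), 3),
            (("TB", "TF"), 3), (("TB", "TF"), 3),
            (("TH", "TA"), 1),
            (("TH", "TF"), 3), (("TH", "TF"), 3),
        ]

    def test_absent_ids_dropped_with_warning(self, toy, caplog):
        net, hits, impls = toy
        ps = collect_shortest_path_set(net, hits + ["GHOST"], impls, 5)
        assert ps.hits == ("TB", "TH")
        assert "absent from network" in caplog.text

    def test_all_hits_absent_fatal(self, toy):
        net, _, impls = toy
        with pytest.raises(ValueError, match="no hit"):
            collect_shortest_path_set(net, ["NO1", "NO2"], impls, 5)

    def test_deterministic_ordering(self, toy):
        net, hits, impls = toy
        a = collect_shortest_path_set(net, hits, impls, 5)
        b = collect_shortest_path_set(net, list(reversed(hits)), list(reversed(impls)), 5)
        assert [p.nodes for p in a.paths] == [p.nodes for p in b.paths]

    def test_known_regulatory_chain_recovered(self):
        # length-3 protein path CDKN1A -> MDM2 -> TCAP -> MSTN on a curated
        # mini-subgraph with a decoy longer route
        net = build_network([
            edge("CDKN1A", "MDM2"), edge("MDM2", "TCAP"), edge("TCAP", "MSTN"),
            edge("CDKN1A", "X1"), edge("X1", "X2"), edge("X2", "X3"), edge("X3", "MSTN"),
        ])
        ps = collect_shortest_path_set(net, ["CDKN1A"], ["MSTN"], 5)
        assert len(ps) == 1
        assert ps.paths[0].nodes == ("CDKN1A", "MDM2", "TCAP", "MSTN")


class TestExtractSubnetwork:
    def test_shared_edge_counted_once(self):
        net = build_network([edge("h1", "a"), edge("h2", "a"), edge("a", "b"), edge("b", "f")])
        ps = collect_shortest_path_set(net, ["H1", "H2"], ["F"], 5)
        sub = extract_subnetwork(ps)
        assert sub.n_edges == 4  # (a,b) and (b,f) shared between the two paths

    def test_single_path_counts(self):
        net = build_network([edge("h", "a"), edge("a", "b"), edge("b", "f")])
        ps = collect_shortest_path_set(net, ["H"], ["F"], 5)
        sub = extract_subnetwork(ps)
        assert (sub.n_nodes, sub.n_edges) == (4, 3)

    def test_toy10_subnetwork_size(self, toy):
        net, hits, impls = toy
        sub = extract_subnetwork(collect_shortest_path_set(net, hits, impls, 5), net)
        assert (sub.n_nodes, sub.n_edges) == (8, 9)
        sub.check_invariants()

    def test_empty_path_set_warns(self, toy, caplog):
        net, _, _ = toy
        ps = collect_shortest_path_set(net, ["TB"], ["TB"], 5)
        sub = extract_subnetwork(ps)
        assert (sub.n_nodes, sub.n_edges) == (0, 0)
        assert "empty path set" in caplog.text


class TestPathSetProperties:
    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(20260921)
        done = 0
        while done < 30:
            net = random_typed_network(rng, int(rng.integers(6, 13)), 0.3)
            if net is None:
                continue
            ids = net.node_ids()
            hits = list(rng.choice(ids, size=min(3, len(ids)), replace=False))
            impls = list(rng.choice(ids, size=min(2, len(ids)), replace=False))
            l_max = int(rng.integers(2, 6))
            try:
                ps = collect_shortest_path_set(net, hits, impls, l_max)
            except ValueError:
                continue
            assert engine_path_set(ps) == brute_force_path_set(net, hits, impls, l_max)
            done += 1

    def test_minimality_within_triples(self, toy):
        net, hits, impls = toy
        ps = collect_shortest_path_set(net, hits, impls, 5)
        by_triple: dict = {}
        for p in ps.paths:
            by_triple.setdefault((p.anchor, p.type_class), set()).add(p.length)
        assert all(len(lengths) == 1 for lengths in by_triple.values())

    def test_monotone_in_lmax(self):
        rng = np.random.default_rng(99)
        net = random_typed_network(rng, 10, 0.3)
        ids = net.node_ids()
        hits, impls = ids[:3], ids[-2:]
        prev: set = set()
        for l_max in (1, 2, 3, 4, 5):
            cur = engine_path_set(collect_shortest_path_set(net, hits, impls, l_max))
            kept_triples = {(h, f, c) for h, f, c, _, _ in prev}
            assert {p for p in cur if (p[0], p[1], p[2]) in kept_triples} >= prev
            prev = cur

    def test_direction_reversal_maps_to_swapped_lists(self):
        rng = np.random.default_rng(7)
        net = random_typed_network(rng, 9, 0.35)
        ids = net.node_ids()
        hits, impls = ids[:3], ids[-2:]
        fwd = engine_path_set(collect_shortest_path_set(net, hits, impls, 4))
        flipped = [
            EdgeRecord(e.target, e.source, e.directed, e.interaction_type, e.provenance)
            for e in net.edges
        ]
        rnet = merge_networks([flipped])
        rev = engine_path_set(collect_shortest_path_set(rnet, impls, hits, 4))
        assert {(f, h, c, tuple(reversed(n)), tuple(reversed(t))) for h, f, c, n, t in fwd} == rev


def test_linear_path_build_validates_simplicity():
    e1 = edge("a", "b")
    e2 = edge("b", "a")
    with pytest.raises(ValueError, match="simple"):
        LinearPath.build(["a", "b", "a"], [e1, e2])
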