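"""Edge-table loading, network merging and degree bookkeeping."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_network, edge
from masterpath.interactome import (
    EdgeRecord,
    NodeRecord,
    load_edge_table,
    load_hit_list,
    load_node_table,
    merge_networks,
    normalize_id,
)


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


HEADER = "source\ttarget\tdirected\tinteraction_type\tprovenance"


class TestLoadEdgeTable:
    def test_self_loops_skipped_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "t.tsv", [
            HEADER,
            "A\tB\tundirected\tppi\tdb1",
            "C\tD\tdirected\ttranscriptional\tdb1",
            "E\tE\tdirected\tppi\tdb1",
        ])
        with caplog.at_level(logging.WARNING):
            recs = load_edge_table(p)
        assert len(recs) == 2
        assert {(r.source, r.target) for r in recs} == {("A", "B"), ("C", "D")}
        assert "self-loop" in caplog.text

    def test_unknown_type_token_is_fatal_naming_line(self, tmp_path):
        p = _write(tmp_path, "t.tsv", [HEADER, "A\tB\tundirected\tppi\tx", "C\tD\tdirected\tTF-gene\tx"])
        with pytest.raises(ValueError, match=r":3: unknown interaction_type 'TF-gene'"):
            load_edge_table(p)

    def test_unknown_directedness_token_is_fatal(self, tmp_path):
        p = _write(tmp_path, "t.tsv", [HEADER, "A\tB\tboth\tppi\tx"])
        with pytest.raises(ValueError, match="directedness"):
            load_edge_table(p)

    def test_duplicates_retained_at_load(self, tmp_path):
        rows = [f"A{i}\tB{i}\tundirected\tppi\tx" for i in range(8)]
        rows += ["A0\tB0\tundirected\tppi\tx", "A1\tB1\tundirected\tppi\tx"]
        p = _write(tmp_path, "t.tsv", [HEADER] + rows)
        assert len(load_edge_table(p)) == 10  # dedup is merge's job

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_edge_table(tmp_path / "absent.tsv")

    def test_identifiers_normalized(self, tmp_path):
        p = _write(tmp_path, "t.tsv", [HEADER, " mdm2 \tHSA-MIR-125B\tdirected\tmirna_mrna\tx"])
        (rec,) = load_edge_table(p)
        assert rec.source == "MDM2"
        assert rec.target == "hsa-mir-125b"


class TestMerge:
    def test_directed_suppresses_undirected_same_pair(self):
        net = merge_networks([
            [edge("A", "B", directed=True)],
            [edge("A", "B", directed=False)],
        ])
        assert net.n_edges == 1
        assert net.edges[0].directed

    def test_exact_duplicates_collapse(self):
        net = merge_networks([[edge("A", "B")], [edge("B", "A")]])  # undirected, same pair
        assert net.n_edges == 1

    def test_precedence_is_pairwise_not_typewise(self):
        net = merge_networks([
            [edge("A", "B", directed=True, itype="transcriptional")],
            [edge("B", "A", directed=True, itype="ppi")],
            [edge("A", "B", directed=False, itype="ppi")],
        ])
        assert net.n_edges == 2
        assert all(e.directed for e in net.edges)

    def test_parallel_types_between_pair_retained(self):
        net = merge_networks([
            [edge("A", "B", directed=True, itype="ppi"),
             edge("A", "B", directed=True, itype="transcriptional")],
        ])
        assert net.n_edges == 2

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError, match="no edges"):
            merge_networks([[]])

    def test_node_class_conflict_resolved_by_precedence(self, caplog):
        with caplog.at_level(logging.WARNING):
            net = merge_networks(
                [[edge("A", "B")]],
                [NodeRecord("A", "gene"), NodeRecord("A", "protein")],
            )
        assert net.nodes["A"].node_class == "protein"
        assert "declared both" in caplog.text

    def test_merge_report_counts(self):
        net = merge_networks([
            [edge("A", "B", directed=True), edge("A", "B", directed=True)],
            [edge("A", "B", directed=False), edge("C", "D")],
        ])
        rep = net.merge_report
        assert (rep.edges_in, rep.duplicates_removed, rep.undirected_suppressed,
                rep.edges_kept) == (4, 1, 1, 2)


class TestDegree:
    def test_isolated_node_via_node_table(self):
        net = build_network([edge("A", "B")], nodes=["Z"])
        assert net.degree("Z") == 0

    def test_hub_after_precedence_suppression(self):
        # hub H: undirected edges to 5 neighbors, one pair also directed;
        # the undirected duplicate to that neighbor is suppressed -> 5 edges
        edges = [edge("H", f"N{i}") for i in range(5)]
        edges.append(edge("H", "N0", directed=True))
        net = merge_networks([edges])
        assert net.degree("H") == 5

    def test_in_plus_out_disjoint_neighbors(self):
        edges = [edge(f"I{i}", "X", directed=True) for i in range(2)]
        edges += [edge("X", f"O{i}", directed=True) for i in range(3)]
        net = merge_networks([edges])
        assert net.degree("X") == 5

    def test_unknown_node_errors_with_id(self, toy):
        net, _, _ = toy
        with pytest.raises(KeyError, match="NOPE"):
            net.degree("NOPE")


def test_normalize_id_rules():
    assert normalize_id("  tp53 ") == "TP53"
    assert normalize_id("HSA-MIR-1") == "hsa-mir-1"
    assert normalize_id("hsa-let-7a") == "hsa-let-7a"


def test_always_directed_types_reject_undirected():
    with pytest.raises(ValueError, match="always directed"):
        EdgeRecord("A", "B", False, "transcriptional", "x")


def test_node_and_hit_list_loading(tmp_path):
    p = tmp_path / "nodes.tsv"
    p.write_text("id\tnode_class\nZ1\tsmall_molecule\nhsa-mir-1\tmiRNA\n")
    recs = load_node_table(p)
    assert [(r.id, r.node_class) for r in recs] == [("Z1", "small_molecule"), ("hsa-mir-1", "miRNA")]
    h = tmp_path / "hits.txt"
    h.write_text("tp53\n# comment\n\nhsa-mir-1\n")
    assert load_hit_list(h) == ["TP53", "hsa-mir-1"]


# -- merge properties --------------------------------------------------------

_ids = st.sampled_from(["A", "B", "C", "D", "E", "F"])
_types = st.sampled_from(["ppi", "transcriptional", "mirna_mrna", "enzymatic"])


@st.composite
def _edge_lists(draw):
    n = draw(st.integers(1, 12))
    edges = []
    for _ in range(n):
        u = draw(_ids)
        v = draw(_ids.filter(lambda x: x != u))
        t = draw(_types)
        directed = True if t in ("transcriptional", "mirna_mrna") else draw(st.booleans())
        edges.append(EdgeRecord(u, v, directed, t, "h"))
    return edges


@given(_edge_lists(), _edge_lists())
def test_merge_invariants_idempotence_and_order_independence(e1, e2):
    ab = merge_networks([e1, e2])
    ab.check_invariants()
    # order independence
    ba = merge_networks([e2, e1])
    assert {e.key() for e in ab.edges} == {e.key() for e in ba.edges}
    # idempotence: merging the merge result is a fixed point
    again = merge_networks([ab.edges])
    assert {e.key() for e in again.edges} == {e.key() for e in ab.edges}
    # degree consistency: each edge contributes exactly two endpoint increments
    assert sum(ab.degree(n) for n in ab.nodes) == 2 * ab.n_edges
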