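"""Reaction-graph topology, circuit closure and product enumeration."""

import pytest

from graphamp.reaction_graph import (
    EdgeKind,
    GraphEdge,
    GraphNode,
    NodeKind,
    ReactionGraph,
    SchemePrimer,
    build_scheme_graph,
    enumerate_products,
    export_dot,
    validate_closure,
)
from graphamp.sequence_core import FragmentComposition
from graphamp.thermo import hairpin_screen

C = FragmentComposition.parse


def test_basic_scheme_closes_circuits_S_and_A():
    g = build_scheme_graph("basic")
    circuits = validate_closure(g)
    assert [c.label for c in circuits] == ["S", "A"]
    assert all(
        any(e.kind is EdgeKind.SELF_FOLDING for e in c.edges)
        and any(e.kind is EdgeKind.PRIMER_EXTENSION for e in c.edges)
        for c in circuits
    )
    assert enumerate_products(g) == [C("3a+1s+2s+3s")]


def test_tailless_scheme_single_antisense_circuit():
    g = build_scheme_graph("tailless")
    assert [c.label for c in validate_closure(g)] == ["A"]
    assert enumerate_products(g) == [C("3a+1s+3s")]


def test_generic_tail_without_target_has_no_blue_box():
    g = build_scheme_graph("generic_tail")
    assert g.nodes(NodeKind.DUPLEX_PRODUCT) == []
    assert validate_closure(g) == []
    assert enumerate_products(g) == []


def test_generic_tail_target_attachment_enables_amplification():
    g = build_scheme_graph("generic_tail").attach_target()
    assert [c.label for c in validate_closure(g)] == ["S", "A"]
    assert enumerate_products(g) == [C("us+1s+2s+ua")]
    assert enumerate_products(g, with_target=False) == []


def test_progressive_graph_circuits_and_motifs():
    g = build_scheme_graph("progressive").attach_target()
    circuits = validate_closure(g)
    assert [c.label for c in circuits] == ["S1", "A1", "S2", "A2"]
    # S1/A1 cycle through the longest motif, S2/A2 through the intermediate
    assert str(circuits[0].motif) == "3a+1s+2s+3s+4s+5s"
    assert str(circuits[2].motif) == "3a+1s+2s+3s+4s"
    assert [str(m) for m in enumerate_products(g, max_len=6)] == [
        "3a+1s+2s+3s",
        "3a+1s+2s+3s+4s",
        "3a+1s+2s+3s+4s+5s",
    ]


def test_multiplex_products_with_either_or_both_initiators():
    for region in (1, 2, 0):
        g = build_scheme_graph("multiplex").attach_target(region)
        products = enumerate_products(g)
        assert len(products) == 2, f"region={region}"
    g = build_scheme_graph("multiplex").attach_target(0)
    assert [c.label for c in validate_closure(g)] == ["S1", "A1", "S2", "A2"]


def test_empty_or_incomplete_primer_set_rejected():
    with pytest.raises(ValueError, match="empty primer set"):
        build_scheme_graph("basic", primers=[])
    with pytest.raises(ValueError, match="missing priming role"):
        build_scheme_graph(
            "basic", primers=[SchemePrimer("inner_antisense", C("2a"))]
        )
    with pytest.raises(ValueError, match="unknown scheme"):
        build_scheme_graph("nonexistent")


def test_no_extension_edges_means_no_circuits():
    g = build_scheme_graph("basic")
    stripped = g.copy()
    drop = [
        (u, v, k)
        for u, v, k, d in stripped._g.edges(keys=True, data=True)
        if d["edge"].kind is EdgeKind.PRIMER_EXTENSION
    ]
    stripped._g.remove_edges_from(drop)
    assert validate_closure(stripped) == []


@pytest.mark.parametrize("scheme", ["basic", "tailless", "generic_tail", "progressive", "multiplex"])
def test_outer_primer_removal_leaves_products_unchanged(scheme):
    g = build_scheme_graph(scheme)
    if scheme in ("generic_tail", "progressive", "multiplex"):
        g.attach_target(0)
    with_outer = enumerate_products(g)
    without = enumerate_products(g.without_outer_primers())
    assert with_outer == without


def test_closure_invariant_under_insertion_order():
    def build(order_reversed: bool) -> ReactionGraph:
        g = ReactionGraph("basic")
        motif = C("3a+1s+2s+3s")
        d = GraphNode(NodeKind.DUPLEX_PRODUCT, motif)
        fs = GraphNode(NodeKind.FOLDED_SENSE, motif)
        fa = GraphNode(NodeKind.FOLDED_ANTISENSE, motif.reverse_complement())
        nodes = [d, fs, fa]
        edges = [
            GraphEdge(EdgeKind.SELF_FOLDING, d.id, fs.id),
            GraphEdge(EdgeKind.SELF_FOLDING, d.id, fa.id),
            GraphEdge(EdgeKind.PRIMER_EXTENSION, fs.id, d.id, "2a"),
            GraphEdge(EdgeKind.PRIMER_EXTENSION, fa.id, d.id, "1s"),
        ]
        if order_reversed:
            nodes, edges = list(reversed(nodes)), list(reversed(edges))
        for n in nodes:
            g.add_node(n, initiator=n.kind is NodeKind.DUPLEX_PRODUCT)
        for e in edges:
            g.add_edge(e)
        return g

    a, b = build(False), build(True)
    assert [(c.label, str(c.motif)) for c in validate_closure(a)] == [
        (c.label, str(c.motif)) for c in validate_closure(b)
    ]
    assert [n.id for n in a.nodes()] == [n.id for n in b.nodes()]


def test_edge_kind_constraints_enforced():
    g = ReactionGraph("basic")
    motif = C("3a+1s+2s+3s")
    d = g.add_node(GraphNode(NodeKind.DUPLEX_PRODUCT, motif))
    p = g.add_node(GraphNode(NodeKind.PRIMER, C("2a")))
    with pytest.raises(ValueError, match="self_folding"):
        g.add_edge(GraphEdge(EdgeKind.SELF_FOLDING, p, d))
    with pytest.raises(ValueError, match="primer_extension"):
        g.add_edge(GraphEdge(EdgeKind.PRIMER_EXTENSION, d, d))


def test_enumerate_products_cap_below_shortest_motif_warns():
    g = build_scheme_graph("basic")
    with pytest.warns(UserWarning, match="max_len"):
        assert enumerate_products(g, max_len=2) == []


def test_enumerated_motifs_fold_and_expose_a_priming_site(gt_design):
    """Rendered motifs self-fold (stem = tail/anti-tail) and their loop
    contains a site matching one of the designed primers' 3' parts."""
    designs, cfg = gt_design
    pset = designs[0].primer_set
    g = pset.build_graph()
    table = g.fragment_table
    from graphamp.sequence_core import compose_sequence, reverse_complement

    for motif in enumerate_products(g):
        rendered = compose_sequence(motif, table)
        fold = hairpin_screen(rendered, params=cfg.thermo).best
        assert fold is not None and fold.dG_kcal < -2.0  # stable designed stem
        loop = rendered[fold.stem_pairs[-1][0] + 1 : fold.stem_pairs[-1][1]]
        assert any(
            p.parts[-1][1] in loop or reverse_complement(p.parts[-1][1]) in loop
            for p in pset.inner_primers
        )


def test_dot_export_carries_kinds_and_compositions():
    g = build_scheme_graph("progressive").attach_target()
    dot = export_dot(g)
    assert dot.startswith('digraph "progressive"')
    assert 'kind="duplex_product"' in dot
    assert 'composition="3a+1s+2s+3s+4s+5s"' in dot
    assert "style=dashed" in dot and "style=solid" in dot
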