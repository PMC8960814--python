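"""Typed reaction graphs for hairpin-mediated isothermal amplification.

The abstraction represents an amplification system as a graph over five
node kinds:

* ``duplex_product`` -- a double-stranded functional-motif amplicon (the
  "blue box"); its composition is the sense strand's fragment composition;
* ``folded_sense`` / ``folded_antisense`` -- single-stranded self-folding
  products (green triangle / green square), each carrying its own 5'->3'
  composition;
* ``primer`` and ``target`` nodes.

and two edge kinds:

* ``self_folding`` (solid arrows): a duplex disassembles into its two
  self-folded strands;
* ``primer_extension`` (dashed arrows): a primer hybridises to an exposed
  priming site on a folded strand (or on the initial target) and is
  extended by a strand-displacing polymerase into a duplex product.

A *circuit* is a minimal closed cycle alternating self-folding and
extension edges; its closure between a duplex and its folded strand is
what sustains amplification.  Sense-side circuits of the longest motif are
numbered first (S1, A1, S2, A2, ...); graphs with a single motif use the
plain S / A labels.

Five scheme topologies are built in: ``basic``, ``tailless``,
``generic_tail``, ``progressive`` and ``multiplex`` (cross-priming over
two target regions).  Generic-tail-style schemes are built *without* any
duplex product -- the graph has no starting point until a target node is
attached, which is exactly how target-dependence is programmed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .sequence_core import (
    Fragment,
    FragmentComposition,
    FragmentLabel,
    SequenceError,
    build_fragment_table,
)

__all__ = [
    "NodeKind",
    "EdgeKind",
    "GraphNode",
    "GraphEdge",
    "Circuit",
    "ReactionGraph",
    "SchemePrimer",
    "SCHEMES",
    "build_scheme_graph",
    "validate_closure",
    "enumerate_products",
    "export_dot",
]


class NodeKind(str, Enum):
    DUPLEX_PRODUCT = "duplex_product"
    FOLDED_SENSE = "folded_sense"
    FOLDED_ANTISENSE = "folded_antisense"
    PRIMER = "primer"
    TARGET = "target"


class EdgeKind(str, Enum):
    SELF_FOLDING = "self_folding"
    PRIMER_EXTENSION = "primer_extension"


@dataclass(frozen=True)
class GraphNode:
    kind: NodeKind
    composition: Optional[FragmentComposition]
    role: str = ""

    @property
    def id(self) -> str:
        comp = str(self.composition) if self.composition is not None else self.role
        return f"{self.kind.value}:{comp}"


@dataclass(frozen=True)
class GraphEdge:
    kind: EdgeKind
    source: str
    sink: str
    priming_label: Optional[str] = None  # extension edges only (e.g. "2a", "F3")
    outer: bool = False  # edge contributed by an outer primer (F3/B3)


@dataclass(frozen=True)
class Circuit:
    """A minimal alternating amplification cycle."""

    label: str  # S, A, S1, A1, ...
    motif: FragmentComposition  # the duplex product's sense composition
    sense: bool  # True for sense-side (triangle) circuits
    edges: Tuple[GraphEdge, ...]


@dataclass(frozen=True)
class SchemePrimer:
    """The minimal primer view the graph needs: a role and a composition."""

    role: str
    composition: FragmentComposition

    @property
    def priming_label(self) -> FragmentLabel:
        """3'-terminal fragment label (the part that primes)."""
        return self.composition.labels[-1]


# canonical inner-primer compositions and required 3' priming labels per scheme
_C = FragmentComposition.parse
SCHEMES = {
    "basic": {
        "primers": [SchemePrimer("inner_antisense", _C("2a")), SchemePrimer("inner_sense", _C("1s"))],
        "has_target_node": False,
        "outer_primers": False,
    },
    "tailless": {
        "primers": [SchemePrimer("inner_sense", _C("1s"))],
        "has_target_node": False,
        "outer_primers": False,
    },
    "generic_tail": {
        "primers": [SchemePrimer("inner_sense", _C("us+1s")), SchemePrimer("inner_antisense", _C("us+2a"))],
        "has_target_node": True,
        "outer_primers": True,
    },
    "progressive": {
        "primers": [
            SchemePrimer("inner_sense", _C("3a+1s")),
            SchemePrimer("inner_antisense", _C("2a")),
            SchemePrimer("inner_antisense", _C("3a")),
            SchemePrimer("inner_antisense", _C("4a")),
            SchemePrimer("inner_antisense", _C("5a")),
        ],
        "has_target_node": True,
        "outer_primers": True,
    },
    "multiplex": {
        "primers": [
            SchemePrimer("cross_P1", _C("3s+2a+1s")),
            SchemePrimer("cross_P2", _C("4s+1a+2s")),
            SchemePrimer("cross_P3", _C("1s+4a+3s")),
            SchemePrimer("cross_P4", _C("2s+3a+4s")),
        ],
        "has_target_node": True,
        "outer_primers": True,
    },
}

_REQUIRED_3P = {
    "basic": {"2a", "1s"},
    "tailless": {"1s"},
    "generic_tail": {"1s", "2a"},
    "progressive": {"1s", "2a", "3a", "4a", "5a"},
    "multiplex": {"1s", "2s", "3s", "4s"},
}


class ReactionGraph:
    """A typed multigraph of amplification species and reactions."""

    def __init__(self, scheme: str, fragments: Optional[Iterable[Fragment]] = None):
        self.scheme = scheme
        self._g = nx.MultiDiGraph()
        self.initiators: set = set()
        self.fragment_table = build_fragment_table(fragments) if fragments else {}

    # -- construction ---------------------------------------------------

    def add_node(self, node: GraphNode, initiator: bool = False) -> str:
        self._g.add_node(node.id, node=node)
        if initiator:
            self.initiators.add(node.id)
        return node.id

    def add_edge(self, edge: GraphEdge) -> None:
        src = self._g.nodes[edge.source]["node"]
        dst = self._g.nodes[edge.sink]["node"]
        if edge.kind is EdgeKind.SELF_FOLDING:
            if src.kind is not NodeKind.DUPLEX_PRODUCT:
                raise ValueError("self_folding edges must leave duplex_product nodes")
            if dst.kind not in (NodeKind.FOLDED_SENSE, NodeKind.FOLDED_ANTISENSE):
                raise ValueError("self_folding edges must enter folded nodes")
        else:
            if src.kind not in (NodeKind.FOLDED_SENSE, NodeKind.FOLDED_ANTISENSE, NodeKind.TARGET):
                raise ValueError("primer_extension edges must leave folded or target nodes")
            if dst.kind is not NodeKind.DUPLEX_PRODUCT:
                raise ValueError("primer_extension edges must enter duplex_product nodes")
        self._g.add_edge(edge.source, edge.sink, edge=edge)

    # -- views ----------------------------------------------------------

    def nodes(self, kind: Optional[NodeKind] = None) -> List[GraphNode]:
        out = [d["node"] for _, d in self._g.nodes(data=True)]
        if kind is not None:
            out = [n for n in out if n.kind is kind]
        return sorted(out, key=lambda n: n.id)

    def edges(self, kind: Optional[EdgeKind] = None) -> List[GraphEdge]:
        out = [d["edge"] for _, _, d in self._g.edges(data=True)]
        if kind is not None:
            out = [e for e in out if e.kind is kind]
        return sorted(out, key=lambda e: (e.source, e.sink, e.priming_label or ""))

    def node(self, node_id: str) -> GraphNode:
        return self._g.nodes[node_id]["node"]

    def copy(self) -> "ReactionGraph":
        clone = ReactionGraph(self.scheme)
        clone._g = self._g.copy()
        clone.initiators = set(self.initiators)
        clone.fragment_table = dict(self.fragment_table)
        return clone

    def without_outer_primers(self) -> "ReactionGraph":
        """Copy with all outer-primer (F3/B3) nodes and edges removed."""
        clone = self.copy()
        drop_edges = [
            (u, v, k)
            for u, v, k, d in clone._g.edges(keys=True, data=True)
            if d["edge"].outer
        ]
        clone._g.remove_edges_from(drop_edges)
        drop_nodes = [
            nid
            for nid, d in clone._g.nodes(data=True)
            if d["node"].kind is NodeKind.PRIMER and d["node"].role.startswith(("F3", "B3"))
        ]
        clone._g.remove_nodes_from(drop_nodes)
        clone.initiators -= set(drop_nodes)
        return clone

    # -- scheme wiring ---------------------------------------------------

    def _duplex(self, motif: FragmentComposition) -> str:
        return self.add_node(GraphNode(NodeKind.DUPLEX_PRODUCT, motif))

    def _folds(self, motif: FragmentComposition) -> Tuple[str, str]:
        fs = self.add_node(GraphNode(NodeKind.FOLDED_SENSE, motif))
        fa = self.add_node(GraphNode(NodeKind.FOLDED_ANTISENSE, motif.reverse_complement()))
        did = GraphNode(NodeKind.DUPLEX_PRODUCT, motif).id
        self.add_edge(GraphEdge(EdgeKind.SELF_FOLDING, did, fs))
        self.add_edge(GraphEdge(EdgeKind.SELF_FOLDING, did, fa))
        return fs, fa

    def _ext(self, src: str, motif: FragmentComposition, label: str, outer: bool = False) -> None:
        did = GraphNode(NodeKind.DUPLEX_PRODUCT, motif).id
        self.add_edge(GraphEdge(EdgeKind.PRIMER_EXTENSION, src, did, priming_label=label, outer=outer))

    def attach_target(self, region: int = 0) -> "ReactionGraph":
        """Attach a target (initiator) node and the duplex machinery it fuels.

        For the ``multiplex`` scheme ``region`` selects which target (1 or 2)
        is introduced; call twice to introduce both.  Schemes whose initiator
        is the hairpin duplex itself (basic, tailless) reject attachment.
        """
        scheme = self.scheme
        has_outer = any(
            n.role.startswith(("F3", "B3")) for n in self.nodes(NodeKind.PRIMER)
        )
        if scheme == "generic_tail":
            motif = _C("us+1s+2s+ua")
            t = self.add_node(GraphNode(NodeKind.TARGET, _C("1s+2s"), role="target"), initiator=True)
            self._duplex(motif)
            fs, fa = self._folds(motif)
            self._ext(t, motif, "1s")
            self._ext(t, motif, "2a")
            if has_outer:
                self._ext(t, motif, "F3", outer=True)
                self._ext(t, motif, "B3", outer=True)
            self._ext(fs, motif, "2a")
            self._ext(fa, motif, "1s")
        elif scheme == "progressive":
            m1, m2, m3 = _C("3a+1s+2s+3s"), _C("3a+1s+2s+3s+4s"), _C("3a+1s+2s+3s+4s+5s")
            t = self.add_node(
                GraphNode(NodeKind.TARGET, _C("1s+2s+3s+4s+5s"), role="target"), initiator=True
            )
            for motif, anti in ((m1, "3a"), (m2, "4a"), (m3, "5a")):
                self._duplex(motif)
                self._ext(t, motif, anti)
            if has_outer:
                self._ext(t, m1, "F3", outer=True)
                self._ext(t, m1, "B3", outer=True)
            fs1, fa1 = self._folds(m1)
            fs2, fa2 = self._folds(m2)
            fs3, fa3 = self._folds(m3)
            # the longest motif feeds every circuit; the core motif (m1) is the
            # terminal product generated inside circuits S1/S2 (and A1/A2)
            for motif, anti in ((m1, "3a"), (m2, "4a"), (m3, "5a")):
                self._ext(fs3, motif, anti)
                self._ext(fa3, motif, "1s")
            for motif, anti in ((m1, "3a"), (m2, "4a")):
                self._ext(fs2, motif, anti)
                self._ext(fa2, motif, "1s")
        elif scheme == "multiplex":
            ma, mb = _C("3a+1s+2s+3s"), _C("1a+3s+4s+1s")
            both_new = not self._g.has_node(GraphNode(NodeKind.DUPLEX_PRODUCT, ma).id)
            if both_new:
                self._duplex(ma)
                self._duplex(mb)
                fsa, faa = self._folds(ma)
                fsb, fab = self._folds(mb)
                self._ext(fsa, ma, "2a")
                self._ext(faa, ma, "2s")
                self._ext(fsa, mb, "3s")
                self._ext(faa, mb, "3s")
                self._ext(fsb, mb, "4a")
                self._ext(fab, mb, "4s")
                self._ext(fsb, ma, "1s")
                self._ext(fab, ma, "1s")
            if region in (0, 1):
                t1 = self.add_node(
                    GraphNode(NodeKind.TARGET, _C("1s+2s"), role="target_region1"), initiator=True
                )
                self._ext(t1, ma, "1s")
                self._ext(t1, ma, "2s")
                if has_outer:
                    self._ext(t1, ma, "F3", outer=True)
                    self._ext(t1, ma, "B3", outer=True)
            if region in (0, 2):
                t2 = self.add_node(
                    GraphNode(NodeKind.TARGET, _C("3s+4s"), role="target_region2"), initiator=True
                )
                self._ext(t2, mb, "3s")
                self._ext(t2, mb, "4s")
                if has_outer:
                    self._ext(t2, mb, "F3", outer=True)
                    self._ext(t2, mb, "B3", outer=True)
        else:
            raise ValueError(
                f"scheme {scheme!r} carries its own initiator duplex; no target to attach"
            )
        return self


def build_scheme_graph(
    scheme: str,
    fragments: Optional[Iterable[Fragment]] = None,
    primers: Optional[Sequence[SchemePrimer]] = None,
    include_outer_primers: Optional[bool] = None,
) -> ReactionGraph:
    """Build the canonical reaction graph for a scheme.

    ``primers`` defaults to the scheme's canonical compositions; when given
    (e.g. from an assembled primer set) they are validated against the
    scheme's required priming roles.  Target-initiated schemes are returned
    *without* a target: no duplex products exist until
    :meth:`ReactionGraph.attach_target` is called.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    spec = SCHEMES[scheme]
    if primers is None:
        primers = spec["primers"]
    primers = list(primers)
    if not primers:
        raise ValueError(f"scheme {scheme!r}: empty primer set")
    got_3p = {str(p.priming_label) for p in primers}
    missing = _REQUIRED_3P[scheme] - got_3p
    if missing:
        raise ValueError(
            f"scheme {scheme!r}: primers missing priming role(s) {sorted(missing)}"
        )
    if scheme == "generic_tail":
        heads = {str(p.composition.labels[0]) for p in primers if p.role.startswith("inner")}
        if heads != {"us"}:
            raise ValueError("generic_tail inner primers must share the 5' tail 'us'")

    graph = ReactionGraph(scheme, fragments)
    for p in primers:
        graph.add_node(GraphNode(NodeKind.PRIMER, p.composition, role=p.role))
    outer = spec["outer_primers"] if include_outer_primers is None else include_outer_primers
    if outer:
        graph.add_node(GraphNode(NodeKind.PRIMER, None, role="F3"))
        graph.add_node(GraphNode(NodeKind.PRIMER, None, role="B3"))

    if scheme == "basic":
        motif = _C("3a+1s+2s+3s")
        graph.add_node(GraphNode(NodeKind.DUPLEX_PRODUCT, motif), initiator=True)
        fs, fa = graph._folds(motif)
        graph._ext(fs, motif, "2a")
        graph._ext(fa, motif, "1s")
    elif scheme == "tailless":
        motif = _C("3a+1s+3s")
        graph.add_node(GraphNode(NodeKind.DUPLEX_PRODUCT, motif), initiator=True)
        fs, fa = graph._folds(motif)
        graph._ext(fa, motif, "1s")  # the sense fold has no priming site left
    # target-initiated schemes stay empty of duplexes until attach_target()
    return graph


# -- circuit validation ----------------------------------------------------


def _alternates(edges: Sequence[GraphEdge]) -> bool:
    kinds = [e.kind for e in edges]
    if EdgeKind.SELF_FOLDING not in kinds or EdgeKind.PRIMER_EXTENSION not in kinds:
        return False
    n = len(kinds)
    return all(kinds[i] is not kinds[(i + 1) % n] for i in range(n))


def validate_closure(graph: ReactionGraph) -> List[Circuit]:
    """All minimal closed cycles alternating self-folding / extension edges.

    A cycle is minimal when no proper subset of its nodes also forms an
    alternating cycle.  Output ordering and labels are canonical and
    independent of node/edge insertion order: motifs by descending fragment
    count (ties lexicographic), sense-side before antisense; a single-motif
    graph uses plain S / A labels, otherwise circuits are numbered S1, A1,
    S2, A2, ...
    """
    g = graph._g
    cycles = []
    for nodes in nx.simple_cycles(g):
        # pick, for each consecutive node pair, each distinct edge kind once
        n = len(nodes)
        choices: List[List[GraphEdge]] = []
        ok = True
        for i in range(n):
            u, v = nodes[i], nodes[(i + 1) % n]
            data = g.get_edge_data(u, v)
            if not data:
                ok = False
                break
            per_kind: dict = {}
            for d in data.values():
                per_kind.setdefault(d["edge"].kind, d["edge"])
            choices.append(list(per_kind.values()))
        if not ok:
            continue
        # small cycles: expand all kind-combinations, keep alternating ones
        def expand(i: int, acc: List[GraphEdge]):
            if i == len(choices):
                if _alternates(acc):
                    cycles.append((tuple(nodes), tuple(acc)))
                return
            for e in choices[i]:
                expand(i + 1, acc + [e])

        expand(0, [])

    # minimality: drop cycles whose node set strictly contains another's
    node_sets = [frozenset(ns) for ns, _ in cycles]
    minimal = []
    for i, (ns, edges) in enumerate(cycles):
        s = node_sets[i]
        if any(other < s for other in node_sets):
            continue
        minimal.append((ns, edges))

    # canonicalise: identify each circuit's duplex motif and strand side
    found = {}
    for ns, edges in minimal:
        duplexes = [
            graph.node(n) for n in ns if graph.node(n).kind is NodeKind.DUPLEX_PRODUCT
        ]
        if not duplexes:
            continue
        motif = duplexes[0].composition
        sense = any(graph.node(n).kind is NodeKind.FOLDED_SENSE for n in ns)
        key = (str(motif), sense)
        if key not in found:
            # canonical edge order: start at the duplex's self-folding edge
            ordered = tuple(sorted(edges, key=lambda e: (e.kind.value, e.source, e.sink)))
            found[key] = (motif, sense, ordered)

    motifs = sorted(
        {str(m): m for m, _, _ in found.values()}.values(),
        key=lambda m: (-len(m), str(m)),
    )
    single = len(motifs) == 1
    out: List[Circuit] = []
    for idx, motif in enumerate(motifs, start=1):
        for sense in (True, False):
            key = (str(motif), sense)
            if key not in found:
                continue
            base = "S" if sense else "A"
            label = base if single else f"{base}{idx}"
            out.append(Circuit(label=label, motif=motif, sense=sense, edges=found[key][2]))
    return out


def enumerate_products(
    graph: ReactionGraph,
    with_target: bool = True,
    max_len: int = 8,
) -> List[FragmentComposition]:
    """Functional-motif compositions reachable from the graph's initiators.

    Walks alternating extension / self-folding steps from every declared
    initiator and collects duplex-product compositions of at most ``max_len``
    fragments, in a deterministic order (ascending length, then text).  With
    ``with_target=False`` the initiators are ignored, so a target-dependent
    graph yields no products -- the programmed no-target silence.
    """
    starts = set(graph.initiators) if with_target else set()
    seen: set = set()
    frontier = list(starts)
    while frontier:
        nid = frontier.pop()
        if nid in seen:
            continue
        seen.add(nid)
        for _, v, d in graph._g.out_edges(nid, data=True):
            if v not in seen:
                frontier.append(v)
    motifs = {
        n.composition
        for nid in seen
        for n in [graph.node(nid)]
        if n.kind is NodeKind.DUPLEX_PRODUCT
    }
    all_duplex = graph.nodes(NodeKind.DUPLEX_PRODUCT)
    if all_duplex and motifs:
        shortest = min(len(n.composition) for n in all_duplex)
        if max_len < shortest:
            warnings.warn(
                f"max_len={max_len} is below the shortest motif ({shortest} fragments); "
                "no products reported",
                stacklevel=2,
            )
    kept = [m for m in motifs if len(m) <= max_len]
    return sorted(kept, key=lambda m: (len(m), str(m)))


def export_dot(graph: ReactionGraph) -> str:
    """Render the graph in DOT format with kind/composition attributes."""
    shape = {
        NodeKind.DUPLEX_PRODUCT: "box",
        NodeKind.FOLDED_SENSE: "triangle",
        NodeKind.FOLDED_ANTISENSE: "square",
        NodeKind.PRIMER: "ellipse",
        NodeKind.TARGET: "diamond",
    }
    lines = [f'digraph "{graph.scheme}" {{']
    for n in graph.nodes():
        comp = str(n.composition) if n.composition is not None else n.role
        lines.append(
            f'  "{n.id}" [shape={shape[n.kind]}, kind="{n.kind.value}", '
            f'composition="{comp}", label="{comp}"];'
        )
    for e in graph.edges():
        style = "solid" if e.kind is EdgeKind.SELF_FOLDING else "dashed"
        attrs = [f"style={style}", f'kind="{e.kind.value}"']
        if e.priming_label:
            attrs.append(f'label="{e.priming_label}"')
        lines.append(f'  "{e.source}" -> "{e.sink}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
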