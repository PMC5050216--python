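"""Network objects built from call lists against a typed interactome.

Node identity is the upper-cased, whitespace-stripped gene symbol; probes are
mapped to symbols before any network stage. Edge types: genetic and
metabolic regulation are directed, protein-protein (pp) contacts undirected.

Stages mirror the analysis flow: the *nucleus* is the interactome subgraph
induced on the called genes; *augmentation* adds undetected interactome
nodes evidenced by links to at least ``min_links`` measured nodes; the
*strongly connected component* isolates the largest mutually reachable
sub-network (largest connected component for a purely undirected pp graph);
``split_by_type`` partitions the edges into the three interaction layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import EDGE_TYPES

__all__ = [
    "TypedGraph",
    "normalize_symbol",
    "build_nucleus",
    "augment",
    "strongly_connected_component",
    "split_by_type",
    "k_core_filter",
]

DIRECTED_TYPES = {"genetic", "metabolic"}


def normalize_symbol(sym: str) -> str:
    return str(sym).strip().upper()


@dataclass
class TypedGraph:
    """Mixed-directedness graph with typed edges and node origin flags.

    Internally a MultiDiGraph: directed edges stored once in their direction,
    pp edges stored once with ``directed=False`` and treated as reciprocal in
    any directed view. Self-loops are rejected.
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    def add_node(self, node: str, origin: str = "measured") -> None:
        self.graph.add_node(normalize_symbol(node), origin=origin)

    def add_edge(self, source: str, target: str, etype: str) -> None:
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        u, v = normalize_symbol(source), normalize_symbol(target)
        if u == v:
            return  # self-loops carry no relational information
        for n in (u, v):
            if n not in self.graph:
                self.graph.add_node(n, origin="measured")
        if self._has_edge(u, v, etype) or (
            etype not in DIRECTED_TYPES and self._has_edge(v, u, etype)
        ):
            return  # keep the edge set duplicate-free
        self.graph.add_edge(u, v, etype=etype, directed=etype in DIRECTED_TYPES)

    def _has_edge(self, u: str, v: str, etype: str) -> bool:
        if not self.graph.has_edge(u, v):
            return False
        return any(d["etype"] == etype for d in self.graph[u][v].values())

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def origin(self, node: str) -> str:
        return self.graph.nodes[node]["origin"]

    def edge_records(self) -> pd.DataFrame:
        rows = [
            (u, d["etype"], v) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "edge_type", "target"])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_types_present(self) -> set[str]:
        return {d["etype"] for _, _, d in self.graph.edges(data=True)}

    def directed_view(self) -> nx.DiGraph:
        """DiGraph with pp edges expanded to both directions."""
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v)
            if not d["directed"]:
                g.add_edge(v, u)
        return g

    def undirected_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((u, v) for u, v, _ in self.graph.edges(data=True))
        return g

    def subgraph_on(self, nodes: set[str]) -> "TypedGraph":
        sub = TypedGraph()
        for n in nodes:
            sub.add_node(n, origin=self.origin(n))
        for u, v, d in self.graph.edges(data=True):
            if u in nodes and v in nodes:
                sub.add_edge(u, v, d["etype"])
        return sub

    def node_attribute_table(self) -> pd.DataFrame:
        und = self.undirected_view()
        comp_id = {}
        for k, comp in enumerate(
            sorted(nx.connected_components(und), key=lambda c: (-len(c), min(c)))
        ):
            for n in comp:
                comp_id[n] = k
        rows = [
            {
                "node": n,
                "origin": self.origin(n),
                "degree": und.degree(n),
                "component": comp_id[n],
            }
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows)


def _normalized_edges(interactome: pd.DataFrame):
    for src, etype, dst in interactome[["source", "edge_type", "target"]].itertuples(
        index=False
    ):
        if etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {etype!r} in interactome")
        yield normalize_symbol(src), etype, normalize_symbol(dst)


def build_nucleus(
    genes, interactome: pd.DataFrame
) -> tuple[TypedGraph, list[str]]:
    """Induced interactome subgraph on the called genes.

    Called genes absent from the interactome are kept as isolated nodes and
    also returned separately for reporting.
    """
    called = {normalize_symbol(g) for g in genes}
    if not called:
        raise ValueError("empty gene list")
    tg = TypedGraph()
    for g in called:
        tg.add_node(g, origin="measured")
    covered: set[str] = set()
    for u, etype, v in _normalized_edges(interactome):
        covered.update((u, v))
        if u in called and v in called:
            tg.add_edge(u, v, etype)
    missing = sorted(called - covered)
    return tg, missing


def augment(
    nucleus: TypedGraph, interactome: pd.DataFrame, min_links: int = 2
) -> TypedGraph:
    """Add undetected connector nodes evidenced by >= ``min_links`` measured
    neighbors, together with their edges to measured nodes.

    Added nodes are flagged ``origin='added'``. The operation is idempotent
    for a fixed ``min_links``: connectors are judged against the measured
    nodes only, so a second pass adds nothing.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    measured = {n for n in nucleus.nodes if nucleus.origin(n) == "measured"}
    neighbor_of: dict[str, set[str]] = {}
    incident: dict[str, list[tuple[str, str, str]]] = {}
    for u, etype, v in _normalized_edges(interactome):
        for outsider, insider in ((u, v), (v, u)):
            if outsider not in measured and insider in measured:
                neighbor_of.setdefault(outsider, set()).add(insider)
                incident.setdefault(outsider, []).append((u, etype, v))
    out = TypedGraph()
    for n in nucleus.nodes:
        out.add_node(n, origin=nucleus.origin(n))
    for u, v, d in nucleus.graph.edges(data=True):
        out.add_edge(u, v, d["etype"])
    added = sorted(n for n, nb in neighbor_of.items() if len(nb) >= min_links)
    for n in added:
        out.add_node(n, origin="added")
        seen = set()
        for u, etype, v in incident[n]:
            key = (u, etype, v)
            if key in seen:
                continue
            seen.add(key)
            other = v if u == n else u
            if other in measured:
                out.add_edge(u, v, etype)
    return out


def strongly_connected_component(tg: TypedGraph) -> TypedGraph:
    """Largest strongly connected component (mutual reachability).

    pp edges count in both directions; a graph with only pp edges reduces to
    its largest connected component. Ties on size break to the component
    containing the lexicographically smallest node.
    """
    if not tg.nodes:
        raise ValueError("empty graph")
    if tg.edge_types_present() & DIRECTED_TYPES:
        comps = list(nx.strongly_connected_components(tg.directed_view()))
    else:
        comps = list(nx.connected_components(tg.undirected_view()))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return tg.subgraph_on(set(best))


def split_by_type(tg: TypedGraph) -> dict[str, TypedGraph]:
    """Partition the edges into the three interaction layers.

    Each output graph keeps only nodes incident to at least one edge of its
    type (isolates dropped); edge counts across the three outputs sum to the
    input edge count.
    """
    out = {t: TypedGraph() for t in EDGE_TYPES}
    for u, v, d in tg.graph.edges(data=True):
        sub = out[d["etype"]]
        for n in (u, v):
            if n not in sub.graph:
                sub.add_node(n, origin=tg.origin(n))
        sub.add_edge(u, v, d["etype"])
    return out


def k_core_filter(tg: TypedGraph, k: int = 2) -> TypedGraph:
    """Optional density filter: nodes of the undirected k-core.

    A labeled approximation of a dense-core reduction; off by default in the
    pipeline and never claimed equivalent to path-motif mining.
    """
    core = nx.k_core(tg.undirected_view(), k=k)
    return tg.subgraph_on(set(core.nodes))
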