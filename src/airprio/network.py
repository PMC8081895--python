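"""Protein interaction network: loading, candidate validation and distances.

The network is the substrate for all proximity scoring and triggering.  Edges
may be directed or undirected and may carry an activating/inhibiting sign.
Internally a :class:`networkx.DiGraph` holds the structure; undirected edges
are stored as a single logical edge and expanded to both arc directions.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from .characterization import CandidatePanel


class EdgeSign(enum.Enum):
    ACTIVATING = "activating"
    INHIBITING = "inhibiting"
    UNSIGNED = "unsigned"


_SIGN_TOKENS = {"+": EdgeSign.ACTIVATING, "-": EdgeSign.INHIBITING, "0": EdgeSign.UNSIGNED}
_SIF_RELATIONS = {"activates": EdgeSign.ACTIVATING, "inhibits": EdgeSign.INHIBITING}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    directed: bool = False
    sign: EdgeSign = EdgeSign.UNSIGNED
    relation: str = ""

    def key(self) -> tuple:
        if self.directed:
            return (self.source, self.target, True)
        a, b = sorted((self.source, self.target))
        return (a, b, False)


class NetworkError(ValueError):
    """Raised for malformed network files or invalid queries."""


class InteractionNetwork:
    """Protein-protein interaction graph with optional direction and sign."""

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[str] = ()):
        self._edges: dict[tuple, Edge] = {}
        self._graph = nx.DiGraph()
        for n in nodes:
            self._graph.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: Edge) -> None:
        if not e.source or not e.target:
            raise NetworkError("edge endpoints must be non-empty node IDs")
        if e.source == e.target:
            return  # self-loops carry no distance information
        self._edges.setdefault(e.key(), e)
        self._graph.add_edge(e.source, e.target)
        if not e.directed:
            self._graph.add_edge(e.target, e.source)

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def degree(self, node: str) -> int:
        """Undirected edges count once; directed edges count in+out."""
        deg = 0
        for e in self._edges.values():
            if e.source == node or e.target == node:
                deg += 1
        return deg

    def graph(self, mode: Literal["undirected", "directed"] = "undirected") -> nx.Graph:
        """Structural view: directed keeps arc orientation (undirected edges
        expand to both arcs); undirected collapses everything."""
        if mode == "directed":
            return self._graph
        return self._graph.to_undirected(as_view=True)

    def parse_stats(self) -> dict:
        n_dir = sum(1 for e in self._edges.values() if e.directed)
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "pct_directed": 100.0 * n_dir / self.n_edges if self.n_edges else 0.0,
        }


def load_network(path: str | Path, dialect: Literal["tsv", "sif"] = "tsv") -> InteractionNetwork:
    """Load an edge list.

    ``tsv``: ``source<TAB>target<TAB>directed(0/1)<TAB>sign(+/-/0)<TAB>relation``
    (trailing columns optional).  ``sif``: ``source<TAB>relation<TAB>target``,
    undirected and unsigned unless relation is ``activates``/``inhibits``.
    Duplicate edge lines are collapsed.
    """
    path = Path(path)
    net = InteractionNetwork()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.rstrip("\n").split("\t")
        if dialect == "sif":
            if len(cells) != 3:
                raise NetworkError(f"{path.name}:{lineno}: SIF line needs 3 fields")
            src, rel, tgt = cells
            sign = _SIF_RELATIONS.get(rel, EdgeSign.UNSIGNED)
            directed = rel in _SIF_RELATIONS
            net.add_edge(Edge(src, tgt, directed=directed, sign=sign, relation=rel))
        else:
            if len(cells) < 2:
                raise NetworkError(f"{path.name}:{lineno}: need at least source, target")
            src, tgt = cells[0], cells[1]
            directed = False
            sign = EdgeSign.UNSIGNED
            relation = ""
            if len(cells) >= 3 and cells[2] != "":
                if cells[2] not in ("0", "1"):
                    raise NetworkError(f"{path.name}:{lineno}: directed flag must be 0/1")
                directed = cells[2] == "1"
            if len(cells) >= 4 and cells[3] != "":
                if cells[3] not in _SIGN_TOKENS:
                    raise NetworkError(f"{path.name}:{lineno}: unknown sign token {cells[3]!r}")
                sign = _SIGN_TOKENS[cells[3]]
            if len(cells) >= 5:
                relation = cells[4]
            net.add_edge(Edge(src, tgt, directed=directed, sign=sign, relation=relation))
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the TSV dialect (stable ordering; round-trips losslessly)."""
    sign_out = {EdgeSign.ACTIVATING: "+", EdgeSign.INHIBITING: "-", EdgeSign.UNSIGNED: "0"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# source\ttarget\tdirected\tsign\trelation\n")
        for e in sorted(net.edges, key=lambda e: e.key()):
            fh.write(f"{e.source}\t{e.target}\t{int(e.directed)}\t{sign_out[e.sign]}\t{e.relation}\n")


def export_sif(net: InteractionNetwork, sif_path: str | Path,
               attrs_path: str | Path | None = None,
               node_attrs: Mapping[str, Mapping[str, object]] | None = None) -> None:
    """Export a Cytoscape-loadable SIF plus an optional node-attribute TSV."""
    rel_out = {EdgeSign.ACTIVATING: "activates", EdgeSign.INHIBITING: "inhibits",
               EdgeSign.UNSIGNED: "interacts"}
    with open(sif_path, "w", encoding="utf-8", newline="\n") as fh:
        for e in sorted(net.edges, key=lambda e: e.key()):
            fh.write(f"{e.source}\t{e.relation or rel_out[e.sign]}\t{e.target}\n")
    if attrs_path is not None and node_attrs:
        keys = sorted({k for attrs in node_attrs.values() for k in attrs})
        with open(attrs_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(["node"] + keys) + "\n")
            for node in sorted(node_attrs):
                fh.write("\t".join([node] + [str(node_attrs[node].get(k, "")) for k in keys]) + "\n")


@dataclass
class CandidateValidationReport:
    """Partition of a candidate panel into network-present, absent and hub
    proteins.  Only absent proteins are excluded by default; hub exclusion is
    opt-in via ``hub_quantile`` < 1."""

    retained: list[str]
    excluded_absent: list[str]
    excluded_hub: list[str]

    def __post_init__(self) -> None:
        parts = [set(self.retained), set(self.excluded_absent), set(self.excluded_hub)]
        total = sum(len(p) for p in parts)
        if total != len(set().union(*parts)):
            raise ValueError("validation report partitions overlap")


def validate_candidates(net: InteractionNetwork, panel: CandidatePanel,
                        hub_quantile: float = 1.0) -> CandidateValidationReport:
    """Split the panel into retained / absent-from-network / hub proteins.

    ``hub_quantile`` is the degree quantile (over all network nodes) above
    which a candidate counts as a hub; 1.0 disables hub exclusion.
    """
    if not 0 < hub_quantile <= 1:
        raise ValueError("hub_quantile must be in (0, 1]")
    if panel.size == 0:
        raise ValueError("empty candidate panel")
    degrees = sorted(net.degree(n) for n in net.nodes)
    cutoff = float("inf")
    if hub_quantile < 1.0 and degrees:
        idx = min(len(degrees) - 1, int(hub_quantile * len(degrees)))
        cutoff = degrees[idx]
    retained, absent, hubs = [], [], []
    for _, gene in panel:
        if gene not in net:
            absent.append(gene)
        elif net.degree(gene) > cutoff:
            hubs.append(gene)
        else:
            retained.append(gene)
    return CandidateValidationReport(retained=retained, excluded_absent=absent,
                                     excluded_hub=hubs)


def shortest_distances(net: InteractionNetwork, source: str,
                       mode: Literal["undirected", "directed"] = "undirected") -> dict[str, int]:
    """BFS hop distances from ``source``; unreachable nodes are absent."""
    if source not in net:
        raise NetworkError(f"source node {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net.graph(mode), source))
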