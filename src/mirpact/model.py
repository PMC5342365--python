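"""Pathway graph data model.

A pathway is modelled as a directed graph whose nodes are genes, miRNAs or
other molecular species and whose edges carry a signed weight (the beta
function of the interaction): positive for activating interactions, negative
for inhibitory ones.  Zero-weight ("irrelevant") edges are pruned by the file
readers before any analysis, so a validated graph never carries them.

Endpoints are pathway outputs: nodes at the end of the reaction chains whose
alteration is linked to phenotypic change.  They are detected automatically as
sinks of the directed graph, or supplied explicitly as a curated id set.
"""
from __future__ import annotations

import enum
import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import networkx as nx

log = logging.getLogger(__name__)


class PathwayError(Exception):
    """Base class for pathway-related failures."""


class PathwayParseError(PathwayError):
    """A pathway file could not be parsed."""


class PathwayValidationError(PathwayError):
    """A pathway violates a structural invariant."""


class NodeClass(str, enum.Enum):
    GENE = "gene"
    MIRNA = "mirna"
    OTHER = "other"


class EdgeClass(str, enum.Enum):
    GENE_GENE = "gene_gene"
    MIRNA_INHIBITION = "mirna_inhibition"
    TF_ACTIVATION = "tf_activation"


@dataclass(frozen=True)
class PathwayNode:
    """A single molecular species in a pathway.

    Ids are namespaced strings (``gene:TP53``, ``mirna:hsa-miR-155``) so the
    bipartite gene/miRNA structure is explicit without an id-mapping service.
    """

    id: str
    node_class: NodeClass = NodeClass.GENE
    is_endpoint: bool = False


@dataclass(frozen=True)
class PathwayEdge:
    """A directed, signed interaction between two pathway nodes.

    ``weight`` is the beta value of the interaction; miRNA inhibition edges
    must be non-positive and TF->miRNA activation edges non-negative.
    """

    source: str
    target: str
    weight: float
    edge_class: EdgeClass = EdgeClass.GENE_GENE

    def __post_init__(self) -> None:
        if self.edge_class is EdgeClass.MIRNA_INHIBITION and self.weight > 0:
            raise PathwayValidationError(
                f"miRNA inhibition edge {self.source}->{self.target} must have "
                f"weight <= 0, got {self.weight}"
            )
        if self.edge_class is EdgeClass.TF_ACTIVATION and self.weight < 0:
            raise PathwayValidationError(
                f"TF activation edge {self.source}->{self.target} must have "
                f"weight >= 0, got {self.weight}"
            )


@dataclass
class PathwayGraph:
    """A directed, signed pathway graph.

    ``nodes`` maps node id to :class:`PathwayNode`; ``edges`` is a list and may
    contain parallel edges between the same ordered pair (they are summed into
    one effective beta at analysis time).
    """

    pathway_id: str
    name: str = ""
    nodes: dict[str, PathwayNode] = field(default_factory=dict)
    edges: list[PathwayEdge] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def build(
        cls,
        pathway_id: str,
        nodes: Iterable[PathwayNode],
        edges: Iterable[PathwayEdge],
        name: str = "",
    ) -> "PathwayGraph":
        node_map: dict[str, PathwayNode] = {}
        for node in nodes:
            if node.id in node_map:
                raise PathwayValidationError(
                    f"duplicate node id {node.id!r} in pathway {pathway_id!r}"
                )
            node_map[node.id] = node
        graph = cls(pathway_id=pathway_id, name=name, nodes=node_map, edges=list(edges))
        graph.validate()
        return graph

    def validate(self) -> None:
        """Check edge endpoints against the node set."""
        for edge in self.edges:
            for nid in (edge.source, edge.target):
                if nid not in self.nodes:
                    raise PathwayValidationError(
                        f"edge {edge.source}->{edge.target} in pathway "
                        f"{self.pathway_id!r} references undeclared node {nid!r}"
                    )

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            pathway_id=self.pathway_id,
            name=self.name,
            nodes=dict(self.nodes),
            edges=list(self.edges),
        )

    # -- queries --------------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    @property
    def endpoints(self) -> set[str]:
        return {n.id for n in self.nodes.values() if n.is_endpoint}

    @property
    def genes(self) -> set[str]:
        return {n.id for n in self.nodes.values() if n.node_class is not NodeClass.MIRNA}

    @property
    def mirnas(self) -> set[str]:
        return {n.id for n in self.nodes.values() if n.node_class is NodeClass.MIRNA}

    def effective_beta(self) -> dict[tuple[str, str], float]:
        """Summed weight per ordered (source, target) pair.

        Parallel edges collapse into a single effective beta; the propagation
        model has exactly one beta per ordered pair.
        """
        eff: dict[tuple[str, str], float] = {}
        for edge in self.edges:
            key = (edge.source, edge.target)
            eff[key] = eff.get(key, 0.0) + edge.weight
        return eff

    def out_degree(self) -> dict[str, int]:
        deg = {nid: 0 for nid in self.nodes}
        for edge in self.edges:
            deg[edge.source] += 1
        return deg

    def upstream(self, node_id: str) -> set[str]:
        """U(n): sources of edges pointing at ``node_id``."""
        return {e.source for e in self.edges if e.target == node_id}

    def downstream(self, node_id: str) -> set[str]:
        """D(n): targets of edges leaving ``node_id``."""
        return {e.target for e in self.edges if e.source == node_id}

    def sinks(self) -> set[str]:
        deg = self.out_degree()
        return {nid for nid, d in deg.items() if d == 0}

    def to_networkx(self) -> nx.DiGraph:
        """Effective-beta view as a networkx DiGraph (parallel edges summed)."""
        g = nx.DiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, node_class=node.node_class.value, is_endpoint=node.is_endpoint)
        for (u, v), w in self.effective_beta().items():
            g.add_edge(u, v, weight=w)
        return g

    # -- transforms -----------------------------------------------------------

    def with_endpoints(self, endpoint_ids: set[str]) -> "PathwayGraph":
        """New graph with ``is_endpoint`` true exactly on ``endpoint_ids``."""
        new_nodes = {
            nid: replace(node, is_endpoint=nid in endpoint_ids)
            for nid, node in self.nodes.items()
        }
        return PathwayGraph(
            pathway_id=self.pathway_id, name=self.name, nodes=new_nodes, edges=list(self.edges)
        )

    def prune_zero_edges(self) -> tuple["PathwayGraph", int]:
        """Drop weight-0 edges; returns (new graph, number dropped)."""
        kept = [e for e in self.edges if e.weight != 0]
        dropped = len(self.edges) - len(kept)
        return (
            PathwayGraph(self.pathway_id, self.name, dict(self.nodes), kept),
            dropped,
        )


def mark_endpoints(graph: PathwayGraph, curated: Optional[set[str]] = None) -> PathwayGraph:
    """Mark pathway endpoints; returns a new graph, input unmodified.

    With a ``curated`` id set, endpoints are exactly the curated ids present in
    the graph (ids absent from the graph are ignored with a warning).  Without
    one, endpoints are the sinks of the directed graph — nodes from which no
    other node can be reached.  miRNA nodes are regulators, not phenotype
    outputs, and are never auto-marked even when they are sinks.
    """
    if curated is not None:
        missing = set(curated) - set(graph.nodes)
        for nid in sorted(missing):
            log.warning(
                "curated endpoint %r not in pathway %s; ignored", nid, graph.pathway_id
            )
        endpoint_ids = set(curated) & set(graph.nodes)
    else:
        endpoint_ids = {
            nid
            for nid in graph.sinks()
            if graph.nodes[nid].node_class is not NodeClass.MIRNA
        }
        if not endpoint_ids and graph.nodes:
            log.warning(
                "pathway %s has no sink nodes (cyclic topology); no endpoints marked",
                graph.pathway_id,
            )
    return graph.with_endpoints(endpoint_ids)


def content_hash(graph: PathwayGraph) -> int:
    """Stable 32-bit hash of the graph's topology (ids, classes, weights).

    Independent of ``pathway_id``/``name``, so the same topology analysed under
    two different ids yields identical derived random streams.
    """
    parts = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        parts.append(f"N\t{node.id}\t{node.node_class.value}\t{int(node.is_endpoint)}")
    for edge in sorted(
        graph.edges, key=lambda e: (e.source, e.target, e.edge_class.value, e.weight)
    ):
        parts.append(
            f"E\t{edge.source}\t{edge.target}\t{edge.weight!r}\t{edge.edge_class.value}"
        )
    return zlib.crc32("\n".join(parts).encode("utf-8"))
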