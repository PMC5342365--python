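import pytest

from mirpact import (
    EdgeClass,
    ExpressionInput,
    NodeClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    mark_endpoints,
)


def build_graph(pathway_id, node_specs, edge_specs, auto_endpoints=True):
    """Compact graph builder for tests.

    node_specs: iterable of ids or (id, NodeClass) tuples.
    edge_specs: iterable of (source, target, weight) or
                (source, target, weight, EdgeClass) tuples.
    """
    nodes = []
    for spec in node_specs:
        if isinstance(spec, tuple):
            nid, ncls = spec
            nodes.append(PathwayNode(nid, ncls))
        else:
            nodes.append(PathwayNode(spec))
    edges = []
    for spec in edge_specs:
        if len(spec) == 4:
            s, t, w, ecls = spec
            edges.append(PathwayEdge(s, t, w, ecls))
        else:
            s, t, w = spec
            edges.append(PathwayEdge(s, t, w))
    graph = PathwayGraph.build(pathway_id, nodes, edges)
    return mark_endpoints(graph) if auto_endpoints else graph


@pytest.fixture
def chain_ab():
    """A -> B with weight +1; endpoint B."""
    return build_graph("path:chain", ["gene:A", "gene:B"], [("gene:A", "gene:B", 1.0)])


@pytest.fixture
def fan_abc():
    """A -> B and A -> C, both +1; endpoints B and C."""
    return build_graph(
        "path:fan",
        ["gene:A", "gene:B", "gene:C"],
        [("gene:A", "gene:B", 1.0), ("gene:A", "gene:C", 1.0)],
    )


def expression(delta, de=None, universe=None):
    delta = dict(delta)
    de = set(de) if de is not None else set(delta)
    universe = set(universe) if universe is not None else set(delta)
    return ExpressionInput(delta_e=delta, de_set=de, universe=universe | set(delta))
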