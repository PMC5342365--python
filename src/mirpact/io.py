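"""Readers and writers for the package's plain-text formats.

Formats
-------
Pathway TSV (UTF-8, tab-separated)
    ``#!`` lines are comments; ``#! key: value`` comments carry pathway
    metadata (``pathway_id``, ``name``).  Node lines are
    ``#node<TAB>id<TAB>node_class<TAB>0|1`` (the last field flags endpoints).
    A header line ``source<TAB>target<TAB>weight<TAB>edge_class`` precedes the
    edge rows.  Zero-weight edges are dropped at load time with a logged count.

KGML
    KEGG Markup Language XML; only ``entry``, ``relation`` and ``group``
    elements are consumed.  Relation subtypes are mapped to signed weights by a
    beta table; unmapped subtypes default to 0 and are pruned.

Expression TSV
    ``node_id<TAB>log_fc<TAB>adj_p`` with a header; rows with adjusted p-value
    below the threshold form the differentially-expressed set.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
from lxml import etree

from .model import (
    EdgeClass,
    NodeClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    PathwayParseError,
    PathwayValidationError,
)
from .perturbation import ExpressionInput

log = logging.getLogger(__name__)

PATHWAY_TSV_HEADER = "source\ttarget\tweight\tedge_class"

#: Default mapping from KGML relation subtype names to signed weights.
DEFAULT_BETA_TABLE: dict[str, float] = {
    "activation": 1.0,
    "expression": 1.0,
    "inhibition": -1.0,
    "repression": -1.0,
}


def _fmt(x: float) -> str:
    return f"{x:.10g}"


# ---------------------------------------------------------------------------
# Pathway TSV
# ---------------------------------------------------------------------------

def read_pathway_tsv(path: Union[str, Path]) -> PathwayGraph:
    """Parse a pathway TSV file into a validated :class:`PathwayGraph`."""
    path = Path(path)
    pathway_id = path.stem
    name = ""
    nodes: list[PathwayNode] = []
    edges: list[PathwayEdge] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!"):
                body = line[2:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "pathway_id" and value:
                        pathway_id = value
                    elif key == "name":
                        name = value
                continue
            if line.startswith("#node"):
                fields = line.split("\t")
                if len(fields) != 4:
                    raise PathwayParseError(
                        f"{path}:{lineno}: node line needs 4 tab-separated fields"
                    )
                _, nid, ncls, flag = fields
                try:
                    node_class = NodeClass(ncls)
                except ValueError as exc:
                    raise PathwayParseError(
                        f"{path}:{lineno}: unknown node class {ncls!r}"
                    ) from exc
                if flag not in ("0", "1"):
                    raise PathwayParseError(
                        f"{path}:{lineno}: endpoint flag must be 0 or 1, got {flag!r}"
                    )
                nodes.append(PathwayNode(nid, node_class, flag == "1"))
                continue
            if line.startswith("#"):
                continue
            if not header_seen:
                if line != PATHWAY_TSV_HEADER:
                    raise PathwayParseError(
                        f"{path}:{lineno}: expected edge header "
                        f"{PATHWAY_TSV_HEADER!r}, got {line!r}"
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise PathwayParseError(
                    f"{path}:{lineno}: edge line needs 4 tab-separated fields"
                )
            source, target, weight_s, ecls = fields
            try:
                weight = float(weight_s)
            except ValueError as exc:
                raise PathwayParseError(
                    f"{path}:{lineno}: weight {weight_s!r} is not a number"
                ) from exc
            try:
                edge_class = EdgeClass(ecls)
            except ValueError as exc:
                raise PathwayParseError(
                    f"{path}:{lineno}: unknown edge class {ecls!r}"
                ) from exc
            try:
                edges.append(PathwayEdge(source, target, weight, edge_class))
            except PathwayValidationError as exc:
                raise PathwayParseError(f"{path}:{lineno}: {exc}") from exc
    graph = PathwayGraph.build(pathway_id, nodes, edges, name=name)
    graph, dropped = graph.prune_zero_edges()
    if dropped:
        log.warning("%s: dropped %d zero-weight edge(s)", path, dropped)
    return graph


def write_pathway_tsv(graph: PathwayGraph, path: Union[str, Path]) -> None:
    """Write a pathway in canonical TSV form (sorted node and edge rows)."""
    path = Path(path)
    lines = [f"#! pathway_id: {graph.pathway_id}"]
    if graph.name:
        lines.append(f"#! name: {graph.name}")
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        lines.append(
            f"#node\t{node.id}\t{node.node_class.value}\t{int(node.is_endpoint)}"
        )
    lines.append(PATHWAY_TSV_HEADER)
    for edge in sorted(
        graph.edges, key=lambda e: (e.source, e.target, e.edge_class.value, e.weight)
    ):
        lines.append(
            f"{edge.source}\t{edge.target}\t{_fmt(edge.weight)}\t{edge.edge_class.value}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

def read_pathway_kgml(
    path: Union[str, Path],
    beta_table: Optional[Mapping[str, float]] = None,
) -> PathwayGraph:
    """Parse a KGML (KEGG XML) pathway into a :class:`PathwayGraph`.

    Gene entries become gene nodes keyed by their KEGG ids (an entry naming
    several ids expands into one node per id); group entries are flattened into
    their member nodes, each inheriting the group's relations.  Relation
    subtypes are weighted by ``beta_table`` (default
    :data:`DEFAULT_BETA_TABLE`); unmapped subtypes get weight 0 and the
    resulting edges are pruned.
    """
    path = Path(path)
    table = dict(DEFAULT_BETA_TABLE)
    if beta_table:
        table.update(beta_table)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PathwayParseError(f"{path}: not well-formed KGML: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", path.stem)
    name = root.get("title", "")

    entry_nodes: dict[str, list[str]] = {}   # entry id -> node ids
    group_members: dict[str, list[str]] = {}  # entry id -> member entry ids
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            names = (entry.get("name") or "").split()
            entry_nodes[eid] = names
        elif etype == "group":
            group_members[eid] = [
                c.get("id") for c in entry.iter("component") if c.get("id")
            ]
        else:
            log.warning("%s: entry %s of type %r skipped", path, eid, etype)

    def resolve(eid: str) -> list[str]:
        if eid in entry_nodes:
            return entry_nodes[eid]
        if eid in group_members:
            out: list[str] = []
            for member in group_members[eid]:
                out.extend(resolve(member))
            return out
        return []

    node_ids: dict[str, None] = {}
    for ids in entry_nodes.values():
        for nid in ids:
            node_ids[nid] = None

    edges: list[PathwayEdge] = []
    for relation in root.iter("relation"):
        sources = resolve(relation.get("entry1", ""))
        targets = resolve(relation.get("entry2", ""))
        for subtype in relation.iter("subtype"):
            weight = table.get(subtype.get("name", ""), 0.0)
            for u in sources:
                for v in targets:
                    edges.append(PathwayEdge(u, v, weight, EdgeClass.GENE_GENE))

    nodes = [PathwayNode(nid, NodeClass.GENE) for nid in node_ids]
    graph = PathwayGraph.build(pathway_id, nodes, edges, name=name)
    graph, dropped = graph.prune_zero_edges()
    if dropped:
        log.warning("%s: dropped %d zero-weight edge(s)", path, dropped)
    return graph


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path: Union[str, Path],
    de_threshold: float = 0.01,
    universe: Optional[set[str]] = None,
) -> ExpressionInput:
    """Read a per-node differential-expression table.

    The DE set consists of rows whose ``adj_p`` is strictly below
    ``de_threshold`` (default 0.01).  The universe defaults to the ids in the
    file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    expected = ["node_id", "log_fc", "adj_p"]
    if list(df.columns[:3]) != expected:
        raise PathwayParseError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    delta_e = dict(zip(df["node_id"], df["log_fc"].astype(float)))
    de_set = set(df.loc[df["adj_p"].astype(float) < de_threshold, "node_id"])
    if universe is None:
        universe = set(delta_e)
    return ExpressionInput(delta_e=delta_e, de_set=de_set, universe=set(universe))


def write_expression_tsv(expr: ExpressionInput, path: Union[str, Path]) -> None:
    """Write an expression input; DE rows get adj_p 0.001, others 0.5."""
    lines = ["node_id\tlog_fc\tadj_p"]
    for nid in sorted(expr.universe):
        lfc = expr.delta_e.get(nid, 0.0)
        adj_p = 0.001 if nid in expr.de_set else 0.5
        lines.append(f"{nid}\t{_fmt(lfc)}\t{adj_p}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "pathway_id",
    "name",
    "impact_factor",
    "acc_total",
    "p_ora",
    "p_perturbation",
    "p_combined",
    "p_adjusted",
]


def write_results_tsv(ranked, path: Union[str, Path]) -> None:
    """Write the ranked per-pathway statistics table."""
    lines = ["\t".join(RESULTS_COLUMNS)]
    for stat in ranked.results:
        lines.append(
            "\t".join(
                [
                    stat.pathway_id,
                    stat.name,
                    _fmt(stat.impact_factor),
                    _fmt(stat.acc_total),
                    _fmt(stat.p_ora),
                    _fmt(stat.p_perturbation),
                    _fmt(stat.p_combined),
                    _fmt(stat.p_adjusted),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_endpoints_tsv(ranked, path: Union[str, Path]) -> None:
    """Write per-endpoint perturbations, one row per (pathway, endpoint)."""
    lines = ["pathway_id\tendpoint_id\tpf"]
    for stat in ranked.results:
        result = ranked.perturbations.get(stat.pathway_id)
        if result is None:
            continue
        for eid in sorted(result.endpoint_pf):
            lines.append(f"{stat.pathway_id}\t{eid}\t{_fmt(result.endpoint_pf[eid])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
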