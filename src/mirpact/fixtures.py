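"""Synthetic pathways, interaction tables and expression inputs.

The generators make the whole pipeline testable without any database access:
random signed pathway topologies, a random miRNA interaction table over their
genes, and expression inputs with a *planted*, sign-coherent signal.

Planting works by assigning fold changes to source-proximal nodes, solving the
propagation system, and recording each endpoint's resulting perturbation as
its own observed fold change (plus optional Gaussian noise).  Expression and
topology therefore agree by construction — the coupling that distinguishes a
real pathway from an identity-scrambled decoy, and the property the endpoint
concordance check quantifies.  The generator emits log-fold-change-level data
directly; it does not emulate count distributions or library normalisation.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .enrichment import (
    InteractionKnowledgeBase,
    InteractionRecord,
    write_interactions_tsv,
)
from .model import (
    EdgeClass,
    NodeClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    mark_endpoints,
)
from .perturbation import ExpressionInput, compute_pf

log = logging.getLogger(__name__)


@dataclass
class FixtureConfig:
    """Knobs of the synthetic benchmark.

    Defaults describe a desk-scale study: ten pathways of 12-18 nodes at 15%
    edge density with a quarter of interactions inhibitory, five miRNAs with
    2-4 validated targets each, planted effects of ~2 log2 units against
    0.25-unit background noise, and roughly 30% of nodes carrying signal.
    ``de_min_abs`` is the |log-FC| below which a planted value is not flagged
    differentially expressed.  ``n_background`` assayed genes outside every
    pathway pad the expression universe, mimicking a transcriptome much
    larger than the pathway collection (they also serve as the decoy
    replacement pool).
    """

    seed: int = 0
    n_pathways: int = 10
    nodes_per_pathway: tuple[int, int] = (12, 18)
    edge_density: float = 0.15
    frac_inhibitory: float = 0.25
    n_mirnas: int = 5
    mirna_targets_per: tuple[int, int] = (2, 4)
    effect_size: float = 2.0
    noise_sd: float = 0.25
    frac_de: float = 0.3
    tf_fraction: float = 0.2
    de_min_abs: float = 0.5
    n_background: int = 300

    def __post_init__(self) -> None:
        for name in ("edge_density",):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("frac_inhibitory", "frac_de", "tf_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nodes_per_pathway", "mirna_targets_per"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range {lo}..{hi} is empty or invalid")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")


def _seed(config: FixtureConfig, *extra: int) -> list[int]:
    return [int(config.seed) & 0x7FFFFFFF, *extra]


def random_pathway(config: FixtureConfig, index: int = 0) -> PathwayGraph:
    """One random connected signed DAG with at least one sink.

    Nodes are ordered and edges only run forward along the order, so the graph
    is acyclic and the last node is always a sink; every node is attached to
    the earlier part of the order, giving weak connectivity.
    """
    rng = np.random.default_rng(_seed(config, 11, index))
    lo, hi = config.nodes_per_pathway
    n = int(rng.integers(lo, hi + 1))
    ids = [f"gene:p{index:02d}n{j:02d}" for j in range(n)]

    def draw_weight() -> float:
        return -1.0 if rng.random() < config.frac_inhibitory else 1.0

    edge_set: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < config.edge_density:
                edge_set.add((i, j))
    # Weak connectivity: attach every node beyond the first to the prefix.
    for j in range(1, n):
        if not any((i, j) in edge_set for i in range(j)):
            edge_set.add((int(rng.integers(0, j)), j))
    edges = [
        PathwayEdge(ids[i], ids[j], draw_weight(), EdgeClass.GENE_GENE)
        for i, j in sorted(edge_set)
    ]
    nodes = [PathwayNode(nid, NodeClass.GENE) for nid in ids]
    graph = PathwayGraph.build(f"path:synth{index:02d}", nodes, edges,
                               name=f"synthetic pathway {index:02d}")
    return mark_endpoints(graph)


def random_pathways(config: FixtureConfig) -> list[PathwayGraph]:
    return [random_pathway(config, i) for i in range(config.n_pathways)]


def random_kb(
    pathways: Sequence[PathwayGraph], config: FixtureConfig
) -> InteractionKnowledgeBase:
    """Random miRNA->gene inhibition table over the pathways' genes, plus a
    ``tf_fraction`` share of TF->miRNA activations."""
    rng = np.random.default_rng(_seed(config, 23))
    genes = sorted(set().union(*(g.genes for g in pathways)) if pathways else set())
    records: list[InteractionRecord] = []
    lo, hi = config.mirna_targets_per
    for k in range(config.n_mirnas):
        mid = f"mirna:m{k:02d}"
        if not genes:
            break
        t = min(int(rng.integers(lo, hi + 1)), len(genes))
        picks = rng.choice(len(genes), size=t, replace=False)
        for idx in sorted(int(i) for i in picks):
            records.append(
                InteractionRecord(mid, genes[idx], EdgeClass.MIRNA_INHIBITION, "synthetic")
            )
        if rng.random() < config.tf_fraction:
            tf = genes[int(rng.integers(0, len(genes)))]
            records.append(
                InteractionRecord(tf, mid, EdgeClass.TF_ACTIVATION, "synthetic")
            )
    return InteractionKnowledgeBase.from_records(records)


def _topo_order(graph: PathwayGraph) -> list[str]:
    import networkx as nx

    g = graph.to_networkx()
    try:
        return [n for n in nx.lexicographical_topological_sort(g)]
    except nx.NetworkXUnfeasible:
        return sorted(graph.nodes)


def _net_influence(graph: PathwayGraph) -> dict[str, float]:
    """Net signed effect of a unit fold change at each node on the pathway
    accumulator (sum over nodes of PF minus own expression)."""
    from .perturbation import PathwaySolver

    solver = PathwaySolver(graph)
    n = len(solver.node_ids)
    if n == 0:
        return {}
    weights = np.where(solver.gene_mask, 1.0, -1.0)
    # acc response to e_u is weights . (A^-1 e_u - e_u); solve the adjoint once.
    y = np.linalg.solve(solver.A.T, weights) - weights
    return {nid: float(y[i]) for i, nid in enumerate(solver.node_ids)}


def planted_signal(
    pathways: Union[PathwayGraph, Sequence[PathwayGraph]],
    config: FixtureConfig,
) -> ExpressionInput:
    """Expression input with sign-coherent planted deregulation.

    Per pathway, the earliest ``frac_de`` share of the topological order
    (excluding endpoints) receives planted fold changes of magnitude around
    ``effect_size``.  Deregulation is coordinated: the pathway gets one random
    orientation and each planted node's sign is chosen so that, propagated
    through the signed topology, its net effect pushes the pathway
    accumulator in that common direction (a node upstream of mostly
    inhibitory chains is planted with the opposite fold change).  Remaining
    interior nodes get N(0, noise_sd) background.  Endpoint fold changes are
    then set to the perturbation each endpoint actually receives from that
    input (plus noise), so with zero noise prediction and observation agree
    exactly.  Nodes are flagged DE when |log-FC| >= ``de_min_abs``;
    background nodes are never flagged.
    """
    if isinstance(pathways, PathwayGraph):
        pathways = [pathways]
    rng = np.random.default_rng(_seed(config, 37))
    delta: dict[str, float] = {}
    de: set[str] = set()
    universe: set[str] = set()
    for graph in pathways:
        universe |= set(graph.nodes)
        endpoints = graph.endpoints
        order = _topo_order(graph)
        interior = [nid for nid in order if nid not in endpoints]
        n_plant = max(1, round(config.frac_de * len(graph.nodes)))
        planted = interior[:n_plant]
        pathway_sign = 1.0 if rng.random() < 0.5 else -1.0
        influence = _net_influence(graph)
        local: dict[str, float] = {}
        for nid in planted:
            mag = (abs(rng.normal(config.effect_size, config.effect_size / 4.0))
                   if config.effect_size > 0 else 0.0)
            orient = influence.get(nid, 0.0)
            sign = pathway_sign * (math.copysign(1.0, orient) if orient != 0.0 else 1.0)
            local[nid] = sign * mag
        for nid in interior[n_plant:]:
            local[nid] = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        probe = ExpressionInput(
            delta_e=dict(local), de_set=set(), universe=set(graph.nodes)
        )
        pf = compute_pf(graph, probe)
        for eid in sorted(endpoints):
            noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            local[eid] = pf.pf[eid] + noise
        for nid, v in local.items():
            delta[nid] = v
            flagged = (nid in planted or nid in endpoints) and abs(v) >= config.de_min_abs
            if flagged:
                de.add(nid)
    for b in range(config.n_background):
        nid = f"gene:bg{b:04d}"
        if nid in universe:
            continue
        universe.add(nid)
        delta[nid] = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
    return ExpressionInput(delta_e=delta, de_set=de, universe=universe)


def null_calibration_pvalues(
    n_inputs: int = 200,
    seed: int = 0,
    n_nodes: tuple[int, int] = (90, 110),
    n_universe: int = 1000,
    n_de: int = 100,
    n_reps: int = 1000,
) -> list[float]:
    """Combined p-values for one pathway under a global null.

    Each simulated input draws a random DE subset of the universe and gives
    its members i.i.d. standard-normal fold changes (all other features
    unchanged), so the observed assignment of values to pathway positions is
    exchangeable with the permutation null and the combined p-value should be
    approximately uniform.  Used to check the calibration of the significance
    machinery.
    """
    from .perturbation import PathwaySolver, compute_accumulators, compute_pf
    from .significance import (
        PermutationConfig,
        combine_pvalues,
        ora_pvalue,
        permutation_null,
    )

    config = FixtureConfig(
        seed=seed, n_pathways=1, nodes_per_pathway=n_nodes, edge_density=0.05
    )
    graph = random_pathway(config, index=0)
    solver = PathwaySolver(graph)
    universe = sorted(set(graph.nodes) | {
        f"gene:bg{b:04d}" for b in range(n_universe - len(graph.nodes))
    })
    rng = np.random.default_rng(_seed(config, 53))
    pvals: list[float] = []
    for i in range(n_inputs):
        picks = rng.choice(len(universe), size=n_de, replace=False)
        de_ids = {universe[int(j)] for j in picks}
        delta = {nid: float(rng.normal()) for nid in sorted(de_ids)}
        expr = ExpressionInput(delta_e=delta, de_set=set(de_ids), universe=set(universe))
        pf = compute_pf(graph, expr, solver=solver)
        de_in = expr.de_set & set(graph.nodes)
        p_ora = ora_pvalue(len(de_in), len(graph.nodes), n_de, len(universe))
        pconf = PermutationConfig(n_reps=n_reps, seed=seed * 100003 + i)
        null = permutation_null(graph, expr, pconf, solver=solver)
        acc = compute_accumulators(graph, expr, pf)
        p_pert = null.p_value(acc.acc_gene - acc.acc_mir)
        pvals.append(combine_pvalues(p_ora, p_pert))
    return pvals


def antagonistic_kb(
    pathways: Sequence[PathwayGraph],
    expr: ExpressionInput,
    strength: float = 2.0,
) -> tuple[InteractionKnowledgeBase, ExpressionInput]:
    """Adversarial knowledge base whose miRNA regulation opposes the planted
    signal.

    Each endpoint gets one inhibitory miRNA whose expression is ``strength``
    times the perturbation the endpoint receives from upstream; after
    enrichment the miRNA's inhibition overturns the endpoint's predicted sign
    whenever ``strength > 1``.  Returns the KB together with an expression
    input extended with the miRNA fold changes.
    """
    records: list[InteractionRecord] = []
    delta = dict(expr.delta_e)
    de = set(expr.de_set)
    universe = set(expr.universe)
    for graph in pathways:
        endpoints = graph.endpoints
        masked = ExpressionInput(
            delta_e={nid: (0.0 if nid in endpoints else v) for nid, v in expr.delta_e.items()
                     if nid in graph.nodes},
            de_set=set(),
            universe=set(graph.nodes),
        )
        pf = compute_pf(graph, masked)
        for j, eid in enumerate(sorted(endpoints)):
            upstream = pf.pf[eid]
            if upstream == 0.0 or expr.delta(eid) == 0.0:
                continue
            mid = f"mirna:adv_{graph.pathway_id.replace(':', '_')}_{j}"
            records.append(
                InteractionRecord(mid, eid, EdgeClass.MIRNA_INHIBITION, "antagonistic")
            )
            delta[mid] = strength * upstream
            de.add(mid)
            universe.add(mid)
    kb = InteractionKnowledgeBase.from_records(records)
    return kb, ExpressionInput(delta_e=delta, de_set=de, universe=universe)


def generate_dataset(config: FixtureConfig, outdir: Union[str, Path]) -> dict[str, object]:
    """Emit a complete on-disk dataset: pathway TSVs, KB, expression, manifest."""
    from . import io as mio

    outdir = Path(outdir)
    (outdir / "pathways").mkdir(parents=True, exist_ok=True)
    pathways = random_pathways(config)
    kb = random_kb(pathways, config)
    expr = planted_signal(pathways, config)
    paths: dict[str, object] = {"pathways": []}
    for graph in pathways:
        p = outdir / "pathways" / f"{graph.pathway_id.replace(':', '_')}.tsv"
        mio.write_pathway_tsv(graph, p)
        paths["pathways"].append(str(p))
    kb_path = outdir / "kb.tsv"
    write_interactions_tsv(kb, kb_path)
    paths["kb"] = str(kb_path)
    expr_path = outdir / "expression.tsv"
    mio.write_expression_tsv(expr, expr_path)
    paths["expression"] = str(expr_path)
    manifest = {"generator": "mirpact.fixtures", "config": asdict(config)}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = str(manifest_path)
    return paths
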