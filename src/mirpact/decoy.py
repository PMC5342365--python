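"""Decoy pathways and the real-versus-decoy soundness benchmark.

A decoy pathway keeps the exact structure of a real one — edges, weights,
edge classes, endpoint positions — but every (non-frozen) node id is replaced
by one drawn at random from a replacement universe, class-matched by default.
A method producing biologically meaningful rankings should place real
pathways above their structure-identical but identity-scrambled decoys; the
separation is scored as the area under the ROC curve of the real/decoy labels
against the ranking.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

from sklearn.metrics import roc_auc_score

from .enrichment import InteractionKnowledgeBase
from .model import NodeClass, PathwayEdge, PathwayGraph, PathwayNode
from .perturbation import ExpressionInput
from .significance import PermutationConfig, RankedResults, analyze

import numpy as np

log = logging.getLogger(__name__)

DECOY_SUFFIX = "__decoy"


class SingleClassRankingError(ValueError):
    """ROC is undefined when the ranking contains only one label class."""


@dataclass
class DecoySpec:
    """How to build decoys: replacement universe, class matching, frozen ids.

    ``frozen_ids`` members (complexes, abstract processes, anything meant to
    survive relabelling) are never replaced.
    """

    seed: int
    universe: set[str]
    preserve_classes: bool = True
    frozen_ids: frozenset[str] = frozenset()


def _id_class(node_id: str) -> NodeClass:
    return NodeClass.MIRNA if node_id.startswith("mirna:") else NodeClass.GENE


def make_decoy(graph: PathwayGraph, spec: DecoySpec) -> PathwayGraph:
    """Topology-preserving decoy: same structure, random node identities.

    Deterministic given (spec.seed, pathway id); replacement ids are drawn
    without replacement within the pathway so a decoy never contains duplicate
    ids.
    """
    rng = np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, zlib.crc32(graph.pathway_id.encode())]
    )
    to_replace = [nid for nid in sorted(graph.nodes) if nid not in spec.frozen_ids]
    pool = sorted(set(spec.universe) - set(spec.frozen_ids))
    mapping: dict[str, str] = {nid: nid for nid in spec.frozen_ids if nid in graph.nodes}
    if spec.preserve_classes:
        by_class: dict[NodeClass, list[str]] = {}
        for pid in pool:
            by_class.setdefault(_id_class(pid), []).append(pid)
        need: dict[NodeClass, list[str]] = {}
        for nid in to_replace:
            need.setdefault(graph.nodes[nid].node_class, []).append(nid)
        for ncls, ids in need.items():
            # OTHER nodes draw from the gene side of the universe.
            cls_pool = by_class.get(ncls if ncls is NodeClass.MIRNA else NodeClass.GENE, [])
            if len(cls_pool) < len(ids):
                raise ValueError(
                    f"replacement universe has {len(cls_pool)} ids of class "
                    f"{ncls.value}, need {len(ids)} for pathway {graph.pathway_id}"
                )
            picks = rng.choice(len(cls_pool), size=len(ids), replace=False)
            for nid, idx in zip(ids, picks):
                mapping[nid] = cls_pool[int(idx)]
    else:
        if len(pool) < len(to_replace):
            raise ValueError(
                f"replacement universe of {len(pool)} ids is smaller than the "
                f"{len(to_replace)} nodes of pathway {graph.pathway_id}"
            )
        picks = rng.choice(len(pool), size=len(to_replace), replace=False)
        for nid, idx in zip(to_replace, picks):
            mapping[nid] = pool[int(idx)]

    nodes = [
        PathwayNode(mapping[nid], node.node_class, node.is_endpoint)
        for nid, node in sorted(graph.nodes.items())
    ]
    edges = [
        PathwayEdge(mapping[e.source], mapping[e.target], e.weight, e.edge_class)
        for e in graph.edges
    ]
    return PathwayGraph.build(
        graph.pathway_id + DECOY_SUFFIX,
        nodes,
        edges,
        name=(graph.name + " (decoy)") if graph.name else "",
    )


def is_decoy_id(pathway_id: str) -> bool:
    return pathway_id.endswith(DECOY_SUFFIX)


def _midranks(keys: Sequence) -> list[float]:
    """Mid-ranks (1-based, ties averaged) of arbitrary orderable keys."""
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = [0.0] * len(keys)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and keys[order[j]] == keys[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0  # average of ranks i+1 .. j
        for t in order[i:j]:
            ranks[t] = avg
        i = j
    return ranks


def roc_auc(
    ranked: Sequence[tuple[str, bool]],
    scores: Optional[Sequence[float]] = None,
) -> float:
    """AUC of real/decoy labels against the ranking.

    ``ranked`` lists (pathway_id, is_real) from best to worst rank.  Without
    explicit ``scores``, the score is the negated list position; pass
    mid-ranked scores to share credit among tied ranking statistics.  Equals
    the normalised Mann-Whitney U statistic.
    """
    labels = [1 if is_real else 0 for _pid, is_real in ranked]
    if len(set(labels)) < 2:
        raise SingleClassRankingError(
            "ROC needs at least one real and one decoy pathway"
        )
    if scores is None:
        scores = [-float(i + 1) for i in range(len(ranked))]
    return float(roc_auc_score(labels, list(scores)))


@dataclass
class SoundnessResult:
    auc: float
    ranked: RankedResults
    labels: dict[str, bool]  # pathway_id -> is_real
    rows: list[dict] = field(default_factory=list)


def soundness_experiment(
    pathways: Sequence[PathwayGraph],
    expr: ExpressionInput,
    spec: DecoySpec,
    config: PermutationConfig,
    kb: Optional[InteractionKnowledgeBase] = None,
) -> SoundnessResult:
    """One decoy per real pathway, joint analysis, ROC of the ranking.

    The ranking statistic is the position in the ranked results (adjusted p,
    then descending |Acc|); pathways sharing an identical (p, |Acc|) key share
    a mid-rank.
    """
    if len(pathways) < 1:
        raise ValueError("need at least one real pathway")
    decoys = [make_decoy(p, spec) for p in pathways]
    ranked = analyze(list(pathways) + decoys, expr, config, kb=kb)
    if not ranked.results:
        raise ValueError("analysis produced no rankable pathway")
    keys = [(s.p_adjusted, -abs(s.acc_total)) for s in ranked.results]
    midranks = _midranks(keys)
    pairs = [(s.pathway_id, not is_decoy_id(s.pathway_id)) for s in ranked.results]
    auc = roc_auc(pairs, scores=[-r for r in midranks])
    labels = dict(pairs)
    rows = [
        {
            "pathway_id": s.pathway_id,
            "is_real": int(not is_decoy_id(s.pathway_id)),
            "rank": s.rank,
            "p_adjusted": s.p_adjusted,
            "acc_total": s.acc_total,
        }
        for s in ranked.results
    ]
    return SoundnessResult(auc=auc, ranked=ranked, labels=labels, rows=rows)
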