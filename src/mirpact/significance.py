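"""Statistical significance of pathway perturbation.

Each pathway gets two probabilistic terms:

* an over-representation p-value — the upper-tail hypergeometric probability
  of seeing at least the observed number of differentially expressed nodes in
  a pathway of its size, given the DE count of the whole input universe;
* a permutation p-value for the accumulator — random node subsets of the
  pathway (of the observed DE size) receive log-fold-changes drawn without
  replacement from the input DE pool, the raw accumulator is recomputed for
  each repetition, and the observed value is compared against the null after
  both are centred by the null median (which also serves as E[Acc]).

The two terms are combined by the Stouffer inverse-normal method, adjusted for
multiple testing by Benjamini-Hochberg, and pathways are ranked by adjusted
p-value with ties broken by descending absolute total accumulation.

Per-pathway random streams derive from the global seed and a hash of the
pathway's topology, so results are independent of processing order and
identical topologies analysed under different ids get identical statistics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .enrichment import InteractionKnowledgeBase, enrich_pathway
from .model import PathwayGraph, content_hash
from .perturbation import (
    ExpressionInput,
    PathwaySolver,
    PathwayStatistics,
    PerturbationResult,
    UnsolvablePathwayError,
    compute_accumulators,
    compute_if,
    compute_pf,
    total_accumulation,
)

log = logging.getLogger(__name__)

_P_EPS = 1e-16


class ConcordanceUndefinedError(ValueError):
    """No endpoint carries a non-zero recorded log fold change."""


@dataclass
class PermutationConfig:
    """Permutation-test settings.

    2000 repetitions resolve the p-value to two decimal places; the sampling
    scheme draws node subsets and fold-change values without replacement.
    ``two_sided`` switches the tail count from the literal one-sided
    "null >= observed" rule to ``|null| >= |observed|``, for benchmarks where
    the direction of deregulation is arbitrary.
    """

    n_reps: int = 2000
    seed: int = 0
    sampling: str = "without_replacement"
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.sampling != "without_replacement":
            raise ValueError(f"unsupported sampling scheme {self.sampling!r}")


@dataclass
class PermutationNull:
    """Null accumulator distribution for one pathway."""

    expected_acc: float
    null_raw: np.ndarray
    n_reps: int
    two_sided: bool

    def p_value(self, observed_raw: float) -> float:
        """Tail probability of the observed raw accumulator under the null.

        Both observed and null values are centred by the null median before
        counting; the count ratio is clamped to [1/(n_reps+1), 1] so a value
        beyond every draw never yields an exact zero.
        """
        if self.null_raw.size == 0:
            return 1.0
        obs_c = observed_raw - self.expected_acc
        null_c = self.null_raw - self.expected_acc
        if self.two_sided:
            count = int(np.sum(np.abs(null_c) >= abs(obs_c)))
        else:
            count = int(np.sum(null_c >= obs_c))
        p = count / self.n_reps
        return min(1.0, max(p, 1.0 / (self.n_reps + 1)))


@dataclass
class RankedResults:
    """Analysis output: ranked statistics plus per-pathway perturbations."""

    results: list[PathwayStatistics]
    perturbations: dict[str, PerturbationResult] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


def ora_pvalue(n_de_pathway: int, n_pathway: int, n_de_universe: int, n_universe: int) -> float:
    """Upper-tail hypergeometric over-representation probability P(X >= k).

    Population ``n_universe`` with ``n_de_universe`` DE features; drawing
    ``n_pathway`` pathway members, probability of at least ``n_de_pathway``
    DE members.  Returns 1 for an observation of zero.
    """
    if n_de_pathway < 0 or n_pathway < 0 or n_de_universe < 0 or n_universe < 0:
        raise ValueError("counts must be non-negative")
    if n_pathway > n_universe or n_de_universe > n_universe:
        raise ValueError(
            f"pathway size {n_pathway} and universe DE count {n_de_universe} "
            f"must not exceed the universe size {n_universe}"
        )
    if n_de_pathway > min(n_pathway, n_de_universe):
        raise ValueError(
            f"observed DE count {n_de_pathway} exceeds "
            f"min(pathway size {n_pathway}, universe DE {n_de_universe})"
        )
    if n_de_pathway == 0:
        return 1.0
    p = float(sstats.hypergeom.sf(n_de_pathway - 1, n_universe, n_de_universe, n_pathway))
    return min(1.0, max(p, _P_EPS))


def _pathway_rng(seed: int, graph: PathwayGraph) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, content_hash(graph)])


def permutation_null(
    graph: PathwayGraph,
    expr: ExpressionInput,
    config: PermutationConfig,
    solver: Optional[PathwaySolver] = None,
) -> PermutationNull:
    """Simulate the null accumulator distribution for one pathway.

    Each repetition assigns fold changes from the input DE pool (drawn without
    replacement) to a uniform random node subset of the observed DE size, all
    other nodes set to zero, and recomputes the raw accumulator
    Acc_gene - Acc_mir through the shared factorised solver.  E[Acc] is the
    null median.  Deterministic given (seed, topology, input, config).
    """
    if solver is None:
        solver = PathwaySolver(graph)
    n_de = len(expr.de_set & set(graph.nodes))
    if n_de == 0:
        return PermutationNull(0.0, np.empty(0), config.n_reps, config.two_sided)
    pool = np.asarray(expr.de_pool(), dtype=float)
    if pool.size == 0:
        return PermutationNull(0.0, np.empty(0), config.n_reps, config.two_sided)
    rng = _pathway_rng(config.seed, graph)
    n_nodes = len(solver.node_ids)
    reps = config.n_reps
    k = min(n_de, n_nodes, pool.size)
    # Vectorised without-replacement draws: argsort of uniforms.
    node_pick = np.argsort(rng.random((reps, n_nodes)), axis=1)[:, :k]
    value_pick = np.argsort(rng.random((reps, pool.size)), axis=1)[:, :k]
    rhs = np.zeros((reps, n_nodes))
    np.put_along_axis(rhs, node_pick, pool[value_pick], axis=1)
    rhs = rhs.T  # (n_nodes, reps)
    x = solver.solve(rhs)
    acc_gene, acc_mir = solver.accumulators(x, rhs)
    null_raw = acc_gene - acc_mir
    expected = float(np.median(null_raw))
    return PermutationNull(expected, null_raw, reps, config.two_sided)


def combine_pvalues(p_ora: float, p_perturbation: float) -> float:
    """Stouffer combination: z_i = Phi^-1(1 - p_i), p = 1 - Phi((z1+z2)/sqrt(2))."""
    for p in (p_ora, p_perturbation):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    p1 = min(max(p_ora, _P_EPS), 1.0 - _P_EPS)
    p2 = min(max(p_perturbation, _P_EPS), 1.0 - _P_EPS)
    z = (sstats.norm.isf(p1) + sstats.norm.isf(p2)) / math.sqrt(2.0)
    combined = float(sstats.norm.sf(z))
    return min(1.0, max(combined, _P_EPS))


def adjust_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    if len(pvalues) == 0:
        raise ValueError("empty p-value list")
    adjusted = sstats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
    return [float(min(1.0, p)) for p in adjusted]


def analyze(
    pathways: Sequence[PathwayGraph],
    expr: ExpressionInput,
    config: PermutationConfig,
    kb: Optional[InteractionKnowledgeBase] = None,
) -> RankedResults:
    """Run the full pipeline over a pathway collection.

    Per pathway: optional miRNA enrichment, perturbation factors, ORA p-value,
    permutation null, impact factor, total accumulation and combined p-value;
    then BH adjustment across pathways and ranking by (adjusted p, |Acc|
    descending, id).  Unsolvable pathways are excluded and reported in the
    skip list.
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    results: list[PathwayStatistics] = []
    perturbations: dict[str, PerturbationResult] = {}
    skipped: list[tuple[str, str]] = []
    for base in pathways:
        graph = enrich_pathway(base, kb) if kb is not None else base
        solver = PathwaySolver(graph)
        try:
            pf = compute_pf(graph, expr, solver=solver)
        except UnsolvablePathwayError as exc:
            log.warning("pathway %s skipped: %s", base.pathway_id, exc)
            skipped.append((base.pathway_id, str(exc)))
            continue
        node_ids = set(graph.nodes)
        assayed = node_ids & expr.universe
        de_in = expr.de_set & node_ids
        n_de = len(de_in)
        mean_abs_de = (
            sum(abs(expr.delta(nid)) for nid in de_in) / n_de if n_de else 0.0
        )
        p_ora = (
            ora_pvalue(n_de, len(assayed), len(expr.de_set), len(expr.universe))
            if assayed
            else 1.0
        )
        null = permutation_null(graph, expr, config, solver=solver)
        acc = compute_accumulators(graph, expr, pf)
        raw = acc.acc_gene - acc.acc_mir
        acc_total = total_accumulation(acc.acc_gene, acc.acc_mir, null.expected_acc)
        # Exact identity of the total accumulation, by construction.
        assert acc_total == acc.acc_gene - acc.acc_mir - null.expected_acc
        p_pert = null.p_value(raw)
        impact = compute_if(graph, expr, pf, p_ora)
        p_comb = combine_pvalues(p_ora, p_pert)
        results.append(
            PathwayStatistics(
                pathway_id=base.pathway_id,
                name=graph.name,
                impact_factor=impact,
                acc_gene=acc.acc_gene,
                acc_mir=acc.acc_mir,
                acc_total=acc_total,
                expected_acc=null.expected_acc,
                p_ora=p_ora,
                p_perturbation=p_pert,
                p_combined=p_comb,
                p_adjusted=float("nan"),
                n_de=n_de,
                mean_abs_de=mean_abs_de,
            )
        )
        perturbations[base.pathway_id] = pf
    if results:
        adjusted = adjust_fdr([r.p_combined for r in results])
        for stat, p_adj in zip(results, adjusted):
            stat.p_adjusted = p_adj
        results.sort(key=lambda s: (s.p_adjusted, -abs(s.acc_total), s.pathway_id))
        for rank, stat in enumerate(results, start=1):
            stat.rank = rank
    return RankedResults(results=results, perturbations=perturbations, skipped=skipped)


def endpoint_concordance(
    graph: PathwayGraph,
    expr: ExpressionInput,
    solver: Optional[PathwaySolver] = None,
) -> float:
    """Fraction of endpoints whose predicted perturbation sign matches their
    observed log fold change.

    Perturbation factors are recomputed with every endpoint's own expression
    forced to zero, so an endpoint's prediction rests solely on its upstream
    signal.  Endpoints with zero recorded fold change are not scored; an
    endpoint left with PF = 0 makes no prediction and counts as discordant.
    """
    endpoints = graph.endpoints
    eligible = sorted(e for e in endpoints if expr.delta(e) != 0.0)
    if not eligible:
        raise ConcordanceUndefinedError(
            f"pathway {graph.pathway_id!r} has no endpoint with non-zero log-FC"
        )
    masked_delta = {
        nid: (0.0 if nid in endpoints else v) for nid, v in expr.delta_e.items()
    }
    masked = ExpressionInput(
        delta_e=masked_delta, de_set=set(expr.de_set), universe=set(expr.universe)
    )
    pf = compute_pf(graph, masked, solver=solver)
    hits = sum(
        1
        for e in eligible
        if pf.pf[e] != 0.0 and math.copysign(1.0, pf.pf[e]) == math.copysign(1.0, expr.delta(e))
    )
    return hits / len(eligible)
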