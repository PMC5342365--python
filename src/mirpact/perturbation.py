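"""Node perturbation factors, pathway impact factor, and accumulators.

The perturbation factor of node *n* in pathway *P* is

    PF(n) = dE(n) + sum_{u in U(n)} beta(u, n) / sum_{d in D(u)} |beta(u, d)| * PF(u)

where dE is the log2 fold change, U(n)/D(n) are the upstream/downstream node
sets, and beta is the signed interaction weight.  The normalisation by the
summed absolute outgoing weights distributes an upstream node's perturbation
over its targets without changing the total amount propagated.

The recursion is resolved globally as the linear system (I - M) x = dE with
M[n, u] = beta(u, n) / sum_d |beta(u, d)|, so feedback loops and miRNA
feed-forward loops are handled exactly.  If (I - M) is singular the solver
falls back to the minimum-norm least-squares solution and records the residual
norm; a residual above ``1e-6 * ||dE||`` marks the pathway unsolvable.

Pathway-level summaries:

* impact factor   IF = ln(1 / p_ora) + sum_n |PF(n)| / (mean|dE| * N_de)
* accumulators    Acc_gene = sum_genes (PF - dE), Acc_mir = sum_miRNAs (PF - dE)
* total           Acc = Acc_gene - Acc_mir - E[Acc]

Subtracting each node's own dE removes the dominant direct effect of its
expression change; subtracting the miRNA accumulator encodes that up-regulated
miRNAs inhibit (and down-regulated ones activate) the pathway.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .model import NodeClass, PathwayGraph

log = logging.getLogger(__name__)

#: Relative residual above which a least-squares fallback is rejected.
RESIDUAL_RTOL = 1e-6


class UnsolvablePathwayError(RuntimeError):
    """The perturbation linear system has no acceptable solution."""


@dataclass
class ExpressionInput:
    """Per-node log fold changes and DE status for one contrast or sample.

    Nodes absent from ``delta_e`` are treated as dE = 0.  ``de_set`` holds the
    ids called differentially expressed upstream (adjusted p below threshold);
    ``universe`` is the full set of assayed ids.
    """

    delta_e: dict[str, float]
    de_set: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.de_set <= set(self.delta_e):
            missing = sorted(self.de_set - set(self.delta_e))[:5]
            raise ValueError(f"DE ids without a log-fold-change: {missing}")
        if not set(self.delta_e) <= self.universe:
            missing = sorted(set(self.delta_e) - self.universe)[:5]
            raise ValueError(f"ids with expression outside the universe: {missing}")

    def delta(self, node_id: str) -> float:
        return self.delta_e.get(node_id, 0.0)

    def de_pool(self) -> list[float]:
        """Log-fold-changes of every DE feature in the input (the permutation pool)."""
        return [self.delta_e[nid] for nid in sorted(self.de_set)]


@dataclass
class SolverInfo:
    method: str
    residual: float


@dataclass
class PerturbationResult:
    """Per-node perturbation factors for one pathway x one input."""

    pathway_id: str
    pf: dict[str, float]
    endpoint_pf: dict[str, float]
    solver_info: SolverInfo


@dataclass
class Accumulators:
    acc_gene: float
    acc_mir: float


@dataclass
class PathwayStatistics:
    """Full per-pathway record produced by the analysis pipeline."""

    pathway_id: str
    name: str
    impact_factor: float
    acc_gene: float
    acc_mir: float
    acc_total: float
    expected_acc: float
    p_ora: float
    p_perturbation: float
    p_combined: float
    p_adjusted: float
    n_de: int
    mean_abs_de: float
    rank: int | None = None


class PathwaySolver:
    """Factorised propagation operator for one pathway, reusable across inputs.

    Builds (I - M) once; observed and permuted expression vectors are then
    solved against the same factorisation (the permutation null needs thousands
    of right-hand sides on an identical topology).
    """

    def __init__(self, graph: PathwayGraph):
        self.graph = graph
        self.node_ids = sorted(graph.nodes)
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}
        n = len(self.node_ids)
        eff = graph.effective_beta()
        norm: dict[str, float] = {}
        for (u, _v), b in eff.items():
            norm[u] = norm.get(u, 0.0) + abs(b)
        M = np.zeros((n, n))
        for (u, v), b in eff.items():
            if b != 0.0 and norm[u] > 0.0:
                M[self.index[v], self.index[u]] = b / norm[u]
        self.A = np.eye(n) - M
        self.gene_mask = np.array(
            [graph.nodes[nid].node_class is not NodeClass.MIRNA for nid in self.node_ids]
        )
        self.mir_mask = ~self.gene_mask
        # LU with explicit singularity detection on the U diagonal.
        if n:
            with warnings.catch_warnings():
                # Singularity is detected below and handled by the pinv path.
                warnings.simplefilter("ignore", sla.LinAlgWarning)
                lu, piv = sla.lu_factor(self.A, check_finite=False)
            tiny = max(1.0, float(np.abs(self.A).max())) * 1e-10
            if float(np.abs(np.diag(lu)).min()) <= tiny:
                self.method = "min-norm-lstsq"
                self._pinv = np.linalg.pinv(self.A)
                self._lu = None
            else:
                self.method = "lu"
                self._lu = (lu, piv)
                self._pinv = None
        else:
            self.method = "lu"
            self._lu = None
            self._pinv = None

    def rhs_vector(self, expr: ExpressionInput) -> np.ndarray:
        return np.array([expr.delta(nid) for nid in self.node_ids])

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve (I - M) x = rhs for a vector or a matrix of columns."""
        if rhs.shape[0] == 0:
            return rhs.copy()
        if self._lu is not None:
            return sla.lu_solve(self._lu, rhs, check_finite=False)
        return self._pinv @ rhs

    def residual(self, x: np.ndarray, rhs: np.ndarray) -> float:
        if rhs.size == 0:
            return 0.0
        return float(np.linalg.norm(self.A @ x - rhs))

    def accumulators(self, x: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(acc_gene, acc_mir) column-wise for solution(s) ``x`` against ``rhs``."""
        diff = x - rhs
        return self.gene_mask @ diff, self.mir_mask @ diff


def compute_pf(
    graph: PathwayGraph,
    expr: ExpressionInput,
    solver: PathwaySolver | None = None,
) -> PerturbationResult:
    """Solve the perturbation system for one pathway against one input."""
    if solver is None:
        solver = PathwaySolver(graph)
    rhs = solver.rhs_vector(expr)
    if not np.any(rhs):
        x = np.zeros_like(rhs)
        info = SolverInfo(method=solver.method, residual=0.0)
    else:
        x = solver.solve(rhs)
        resid = solver.residual(x, rhs)
        tol = RESIDUAL_RTOL * float(np.linalg.norm(rhs))
        if resid > tol:
            raise UnsolvablePathwayError(
                f"pathway {graph.pathway_id!r}: residual {resid:.3g} exceeds "
                f"tolerance {tol:.3g} (method {solver.method})"
            )
        info = SolverInfo(method=solver.method, residual=resid)
    pf = {nid: float(x[i]) for i, nid in enumerate(solver.node_ids)}
    endpoint_pf = {eid: pf[eid] for eid in graph.endpoints}
    return PerturbationResult(graph.pathway_id, pf, endpoint_pf, info)


def compute_if(
    graph: PathwayGraph,
    expr: ExpressionInput,
    pf: PerturbationResult,
    p_ora: float,
) -> float:
    """Impact factor: ORA evidence plus normalised total absolute perturbation.

    Returns 0 (with a logged note) when the pathway has no DE node or the mean
    absolute fold change vanishes: an unexpressed pathway is a valid,
    uninteresting result, not an error.
    """
    if not 0.0 < p_ora <= 1.0:
        raise ValueError(f"p_ora must be in (0, 1], got {p_ora}")
    de_in = expr.de_set & set(graph.nodes)
    n_de = len(de_in)
    if n_de == 0:
        log.info("pathway %s: no DE nodes, impact factor set to 0", graph.pathway_id)
        return 0.0
    mean_abs = sum(abs(expr.delta(nid)) for nid in de_in) / n_de
    if mean_abs == 0.0:
        log.info(
            "pathway %s: zero mean |log-FC| over DE nodes, impact factor set to 0",
            graph.pathway_id,
        )
        return 0.0
    total_abs_pf = sum(abs(v) for v in pf.pf.values())
    return math.log(1.0 / p_ora) + total_abs_pf / (mean_abs * n_de)


def compute_accumulators(
    graph: PathwayGraph,
    expr: ExpressionInput,
    pf: PerturbationResult,
) -> Accumulators:
    """Partial accumulators: sum of (PF - dE) over genes and over miRNAs."""
    acc_gene = 0.0
    acc_mir = 0.0
    for nid, node in graph.nodes.items():
        contribution = pf.pf[nid] - expr.delta(nid)
        if node.node_class is NodeClass.MIRNA:
            acc_mir += contribution
        else:
            acc_gene += contribution
    return Accumulators(acc_gene=acc_gene, acc_mir=acc_mir)


def total_accumulation(acc_gene: float, acc_mir: float, expected_acc: float) -> float:
    """Acc = Acc_gene - Acc_mir - E[Acc]."""
    return acc_gene - acc_mir - expected_acc
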