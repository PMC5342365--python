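"""ORA p-value, permutation null, p-value combination, FDR, ranking and
endpoint concordance."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from mirpact import (
    ConcordanceUndefinedError,
    EdgeClass,
    FixtureConfig,
    InteractionKnowledgeBase,
    InteractionRecord,
    NodeClass,
    PermutationConfig,
    PermutationNull,
    adjust_fdr,
    analyze,
    combine_pvalues,
    endpoint_concordance,
    enrich_pathway,
    ora_pvalue,
    permutation_null,
    planted_signal,
    random_pathways,
)

from conftest import build_graph, expression


def hypergeom_tail_bruteforce(k, n, K, N):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestOraPvalue:
    def test_zero_observed_gives_one(self):
        assert ora_pvalue(0, 10, 50, 1000) == 1.0

    def test_all_draws_successes(self):
        assert ora_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    @pytest.mark.parametrize("k,n,K,N", [(2, 4, 5, 20), (3, 8, 10, 40), (1, 3, 2, 12)])
    def test_matches_enumeration(self, k, n, K, N):
        assert ora_pvalue(k, n, K, N) == pytest.approx(
            hypergeom_tail_bruteforce(k, n, K, N), rel=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ora_pvalue(6, 5, 10, 20)
        with pytest.raises(ValueError):
            ora_pvalue(1, 30, 10, 20)


class TestPermutationNull:
    def graph_and_expr(self):
        g = build_graph(
            "path:perm",
            [f"gene:n{i}" for i in range(6)],
            [
                ("gene:n0", "gene:n1", 1.0),
                ("gene:n0", "gene:n2", 1.0),
                ("gene:n1", "gene:n3", 1.0),
                ("gene:n2", "gene:n4", -1.0),
                ("gene:n3", "gene:n5", 1.0),
            ],
        )
        expr = expression(
            {"gene:n0": 2.0, "gene:n1": -1.0},
            de={"gene:n0", "gene:n1"},
            universe={f"gene:n{i}" for i in range(6)},
        )
        return g, expr

    def test_no_de_short_circuits(self):
        g, _ = self.graph_and_expr()
        expr = expression({}, de=set(), universe=set(g.nodes))
        null = permutation_null(g, expr, PermutationConfig(n_reps=100, seed=1))
        assert null.expected_acc == 0.0
        assert null.p_value(0.0) == 1.0

    def test_reproducible_for_fixed_seed(self):
        g, expr = self.graph_and_expr()
        cfg = PermutationConfig(n_reps=500, seed=42)
        a = permutation_null(g, expr, cfg)
        b = permutation_null(g, expr, cfg)
        assert np.array_equal(a.null_raw, b.null_raw)
        c = permutation_null(g, expr, PermutationConfig(n_reps=500, seed=43))
        assert not np.array_equal(a.null_raw, c.null_raw)
        assert abs(a.expected_acc - c.expected_acc) < 2.0  # Monte-Carlo jitter only

    def test_symmetric_pool_has_near_zero_median(self):
        g, _ = self.graph_and_expr()
        expr = expression(
            {"gene:n0": 1.0, "gene:n1": -1.0},
            de={"gene:n0", "gene:n1"},
            universe=set(g.nodes),
        )
        null = permutation_null(g, expr, PermutationConfig(n_reps=2000, seed=3))
        assert abs(null.expected_acc) < 0.1

    def test_observed_beyond_all_draws_hits_floor(self):
        g, expr = self.graph_and_expr()
        null = permutation_null(g, expr, PermutationConfig(n_reps=2000, seed=7))
        assert null.null_raw.size == 2000
        extreme = float(null.null_raw.max()) + 1.0
        assert null.p_value(extreme) == pytest.approx(1 / 2001)

    def test_two_sided_counts_magnitude(self):
        null = PermutationNull(
            expected_acc=0.0,
            null_raw=np.array([-3.0, -1.0, 0.0, 1.0, 3.0]),
            n_reps=5,
            two_sided=True,
        )
        assert null.p_value(2.0) == pytest.approx(2 / 5)
        one_sided = PermutationNull(
            expected_acc=0.0, null_raw=null.null_raw, n_reps=5, two_sided=False
        )
        assert one_sided.p_value(2.0) == pytest.approx(1 / 5)


class TestCombineAndFdr:
    def test_stouffer_identity_on_half(self):
        assert combine_pvalues(0.5, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_stouffer_reinforces_evidence(self):
        z = sstats.norm.isf(0.05)
        want = float(sstats.norm.sf(2 * z / math.sqrt(2)))
        assert combine_pvalues(0.05, 0.05) == pytest.approx(want, rel=1e-9)
        assert want == pytest.approx(0.0100, abs=5e-4)

    def test_clamped_at_one(self):
        assert combine_pvalues(1.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_bh_worked_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_single_test_unchanged(self):
        assert adjust_fdr([0.5]) == [0.5]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=20))
    def test_bh_never_decreases_and_is_permutation_equivariant(self, ps):
        adjusted = adjust_fdr(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adjusted, ps))
        assert all(a <= 1.0 for a in adjusted)
        perm = list(reversed(range(len(ps))))
        permuted = adjust_fdr([ps[i] for i in perm])
        assert permuted == pytest.approx([adjusted[i] for i in perm])


class TestAnalyze:
    def test_no_de_nodes_degenerate(self, chain_ab):
        expr = expression({}, de=set(), universe=set(chain_ab.nodes))
        ranked = analyze([chain_ab], expr, PermutationConfig(n_reps=50, seed=1))
        (stat,) = ranked.results
        assert stat.p_adjusted == 1.0
        assert stat.acc_total == 0.0
        assert stat.impact_factor == 0.0

    def test_saturated_pathway_ranks_first(self):
        cfg = FixtureConfig(seed=9, n_pathways=2, n_background=50)
        p1, p2 = random_pathways(cfg)
        sat = planted_signal(p1, cfg)
        # Merge with an empty signal over p2's nodes: p2 untouched.
        expr = expression(
            dict(sat.delta_e),
            de=sat.de_set,
            universe=sat.universe | set(p2.nodes),
        )
        ranked = analyze(
            [p2, p1], expr, PermutationConfig(n_reps=500, seed=1, two_sided=True)
        )
        assert ranked.results[0].pathway_id == p1.pathway_id
        assert ranked.results[0].rank == 1

    def test_identical_topology_under_two_ids_gets_identical_statistics(self, fan_abc):
        twin = fan_abc.copy()
        twin.pathway_id = "path:fan-twin"
        expr = expression({"gene:A": 2.0, "gene:B": 1.0}, de={"gene:A"})
        ranked = analyze([fan_abc, twin], expr, PermutationConfig(n_reps=300, seed=5))
        a, b = sorted(ranked.results, key=lambda s: s.pathway_id)
        assert a.p_perturbation == b.p_perturbation
        assert a.acc_total == b.acc_total
        assert a.p_combined == b.p_combined

    def test_unsolvable_pathway_lands_in_skip_list(self, chain_ab):
        cyclic = build_graph(
            "path:cycle", ["gene:A", "gene:B"],
            [("gene:A", "gene:B", 1.0), ("gene:B", "gene:A", 1.0)],
        )
        expr = expression({"gene:A": 1.0}, de={"gene:A"},
                          universe={"gene:A", "gene:B"})
        ranked = analyze([chain_ab, cyclic], expr, PermutationConfig(n_reps=50, seed=1))
        assert [pid for pid, _ in ranked.skipped] == ["path:cycle"]
        assert len(ranked.results) == 1

    def test_empty_kb_run_equals_unenriched_run(self, fan_abc):
        expr = expression({"gene:A": 2.0}, de={"gene:A"})
        cfg = PermutationConfig(n_reps=200, seed=2)
        plain = analyze([fan_abc], expr, cfg).results[0]
        with_empty_kb = analyze(
            [fan_abc], expr, cfg,
            kb=InteractionKnowledgeBase.from_records(
                [InteractionRecord("mirna:m9", "gene:Z", EdgeClass.MIRNA_INHIBITION)]
            ),
        ).results[0]
        assert with_empty_kb.acc_mir == 0.0
        assert with_empty_kb.acc_total == plain.acc_total
        assert with_empty_kb.p_combined == plain.p_combined

    def test_ranking_keys(self):
        # Adjusted p ascending, then |Acc| descending.
        cfg = FixtureConfig(seed=4)
        pathways = random_pathways(cfg)
        expr = planted_signal(pathways, cfg)
        ranked = analyze(pathways, expr, PermutationConfig(n_reps=300, seed=4))
        keys = [(s.p_adjusted, -abs(s.acc_total)) for s in ranked.results]
        assert keys == sorted(keys)


class TestEndpointConcordance:
    def test_activating_chain_concordant(self, chain_ab):
        expr = expression({"gene:A": 2.0, "gene:B": 1.0})
        assert endpoint_concordance(chain_ab, expr) == 1.0

    def test_inhibitory_chain_discordant(self):
        g = build_graph("p", ["gene:A", "gene:B"], [("gene:A", "gene:B", -1.0)])
        expr = expression({"gene:A": 2.0, "gene:B": 1.0})
        assert endpoint_concordance(g, expr) == 0.0

    def test_zero_pf_endpoint_counts_as_discordant(self, chain_ab):
        expr = expression({"gene:B": 1.0})  # no upstream signal at all
        assert endpoint_concordance(chain_ab, expr) == 0.0

    def test_no_eligible_endpoint_is_signalled(self, chain_ab):
        expr = expression({"gene:A": 2.0})
        with pytest.raises(ConcordanceUndefinedError):
            endpoint_concordance(chain_ab, expr)

    def test_silent_mirnas_leave_concordance_unchanged(self):
        cfg = FixtureConfig(seed=21, noise_sd=0.0, n_pathways=3)
        pathways = random_pathways(cfg)
        expr = planted_signal(pathways, cfg)
        kb = InteractionKnowledgeBase.from_records(
            [
                InteractionRecord(
                    "mirna:quiet", sorted(pathways[0].genes)[0],
                    EdgeClass.MIRNA_INHIBITION, "test",
                )
            ]
        )
        for g in pathways:
            plain = endpoint_concordance(g, expr)
            enriched = endpoint_concordance(enrich_pathway(g, kb), expr)
            # The added miRNA has dE = 0, so no miRNA-mediated term changes.
            assert enriched == plain
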