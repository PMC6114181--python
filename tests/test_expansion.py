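import numpy as np
import pandas as pd
import pytest

from mirmediation.bn_core import (
    FamilyScoreCache,
    NetworkStructure,
    NodeRole,
    enumerate_constrained_structures,
    select_best,
)
from mirmediation.data_io import SDPTable
from mirmediation.expansion import (
    apply_retention,
    bootstrap_average,
    group_by_locus,
    hill_climb,
)
from mirmediation.mediation import MediationDecision
from mirmediation.synthetic_data import ScenarioSpec, simulate_quadruple


def _decision(sdp, pheno="p1", mirna="m1", gene="g1", gene_pass=True):
    return MediationDecision(
        sdp_id=sdp, mirna_id=mirna, gene_id=gene, phenotype_id=pheno,
        best_overall=None, best_mediated_bic=0.0, best_nonmediated_bic=-5.0,
        delta_mediation=5.0, mediation_pass=True,
        best_both_in_path_bic=0.0, best_mirna_only_in_path_bic=0.0,
        delta_gene=0.0, gene_pass=gene_pass, selected_nodes=(sdp, mirna, pheno),
    )


def _sdp_table(midpoints):
    """midpoints: dict sdp_id -> (chrom, bp)"""
    ids = list(midpoints)
    n = 4
    patterns = pd.DataFrame(
        np.eye(len(ids), n, dtype=int), index=ids,
        columns=[f"s{i}" for i in range(n)],
    )
    return SDPTable(
        patterns=patterns,
        members={i: [f"snp_{i}"] for i in ids},
        spans={i: [(c, int(mid - 1), int(mid + 1))] for i, (c, mid) in midpoints.items()},
        chrom={i: c for i, (c, _) in midpoints.items()},
        validate=False,
    )


class TestLocusGrouping:
    def test_within_window_merged(self):
        table = _sdp_table({"A": ("1", 10e6), "B": ("1", 45e6)})
        groups = group_by_locus([_decision("A"), _decision("B")], table)
        assert len(groups) == 1
        assert groups[0].sdp_ids == ["A", "B"]

    def test_different_chromosomes_split(self):
        table = _sdp_table({"A": ("1", 10e6), "B": ("2", 10e6)})
        groups = group_by_locus([_decision("A"), _decision("B")], table)
        assert len(groups) == 2

    def test_single_linkage_chaining(self):
        table = _sdp_table(
            {"A": ("1", 0.0), "B": ("1", 35e6), "C": ("1", 70e6)}
        )
        groups = group_by_locus(
            [_decision("A"), _decision("B"), _decision("C")], table
        )
        assert len(groups) == 1
        assert groups[0].sdp_ids == ["A", "B", "C"]

    def test_gap_beyond_window_splits(self):
        table = _sdp_table({"A": ("1", 0.0), "B": ("1", 50e6)})
        groups = group_by_locus([_decision("A"), _decision("B")], table)
        assert len(groups) == 2

    def test_gene_only_included_when_gene_pass(self):
        table = _sdp_table({"A": ("1", 1e6)})
        g1 = group_by_locus([_decision("A", gene_pass=True)], table)[0]
        g0 = group_by_locus([_decision("A", gene_pass=False)], table)[0]
        assert g1.gene_ids == ["g1"]
        assert g0.gene_ids == []

    def test_invariant_to_decision_order(self):
        table = _sdp_table({"A": ("1", 0.0), "B": ("1", 35e6)})
        d = [_decision("A"), _decision("B", mirna="m2")]
        g1 = group_by_locus(d, table)
        g2 = group_by_locus(d[::-1], table)
        assert [g.sdp_ids for g in g1] == [g.sdp_ids for g in g2]
        assert [g.mirna_ids for g in g1] == [g.mirna_ids for g in g2]


class TestHillClimb:
    def _roles3(self):
        return [
            NodeRole("S", "sdp_binary_root"),
            NodeRole("M", "continuous_intermediate"),
            NodeRole("P", "continuous_phenotype"),
        ]

    def test_matches_exhaustive_on_three_node_instances(self):
        wins = 0
        n_inst = 50
        for seed in range(n_inst):
            r = np.random.default_rng(seed)
            n = 40
            s = r.binomial(1, 0.5, n).astype(float)
            s[:2] = [0, 1]
            m = 1.2 * s + r.normal(size=n)
            p = 0.8 * m + r.normal(size=n)
            data = pd.DataFrame({"S": s, "M": m, "P": p})
            roles = self._roles3()
            hc = hill_climb(data, roles)
            cache = FamilyScoreCache(data, {x.label: x.kind for x in roles})
            exact = select_best(
                [cache.score(st) for st in enumerate_constrained_structures(roles)]
            )
            wins += hc.bic >= exact.bic - 1e-9
        assert wins / n_inst >= 0.95

    def test_independent_noise_returns_empty_graph_mostly(self, quad_roles):
        # each of the 7 admissible arcs spuriously improves BIC with
        # probability P(chi2_1 > ln n) ~ 0.043 at n = 60, so the expected
        # empty-graph rate is (1 - 0.043)^7 ~ 0.74
        empties = 0
        total_edges = 0
        n_runs = 60
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            n = 60
            data = pd.DataFrame(
                {
                    "S": np.r_[0, 1, r.binomial(1, 0.5, n - 2)].astype(float),
                    "M": r.normal(size=n),
                    "G": r.normal(size=n),
                    "P": r.normal(size=n),
                }
            )
            hc = hill_climb(data, quad_roles)
            empties += len(hc.structure.edges) == 0
            total_edges += len(hc.structure.edges)
        assert empties / n_runs >= 0.65
        assert total_edges / n_runs < 0.6

    def test_optimum_is_fixed_point(self, quad_roles):
        q = simulate_quadruple(ScenarioSpec(seed=3))
        data = q.strain_frame()
        cache = FamilyScoreCache(
            data[["S", "M", "G", "P"]], {x.label: x.kind for x in quad_roles}
        )
        exact = select_best(
            [cache.score(st) for st in enumerate_constrained_structures(quad_roles)]
        )
        hc = hill_climb(data, quad_roles, start=exact.structure)
        assert hc.structure.edges == exact.structure.edges
        assert hc.converged


class TestRetentionRule:
    def test_exactly_half_not_retained(self):
        avg = apply_retention(
            pair_count={("A", "B"): 250}, dir_count={("A", "B"): 250},
            labels=["A", "B"], n_boot=500,
        )
        assert avg.retained_edges == []
        assert avg.dropped_nodes == ["A", "B"]

    def test_just_over_half_retained(self):
        avg = apply_retention(
            pair_count={("A", "B"): 251}, dir_count={("A", "B"): 251},
            labels=["A", "B"], n_boot=500,
        )
        assert avg.retained_edges == [("A", "B")]
        assert avg.dropped_nodes == []

    def test_direction_tie_not_retained(self):
        avg = apply_retention(
            pair_count={("A", "B"): 400},
            dir_count={("A", "B"): 200, ("B", "A"): 200},
            labels=["A", "B"], n_boot=500,
        )
        assert avg.retained_edges == []

    def test_direction_denominator_modes(self):
        # present 300/500, direction 160/140: conditional freq 160/300 > 0.5
        # retained under edge_present; unconditional 160/500 < 0.5 dropped
        kw = dict(
            pair_count={("A", "B"): 300},
            dir_count={("A", "B"): 160, ("B", "A"): 140},
            labels=["A", "B"], n_boot=500,
        )
        assert apply_retention(**kw).retained_edges == [("A", "B")]
        assert (
            apply_retention(**kw, direction_denominator="all_bootstraps").retained_edges
            == []
        )

    def test_cycle_resolved_by_presence_order(self):
        # A->B, B->C, C->A all retained individually; lowest-presence edge skipped
        avg = apply_retention(
            pair_count={("A", "B"): 500, ("B", "C"): 450, ("A", "C"): 400},
            dir_count={("A", "B"): 500, ("B", "C"): 450, ("C", "A"): 400},
            labels=["A", "B", "C"], n_boot=500,
        )
        assert ("C", "A") not in avg.retained_edges
        assert ("A", "B") in avg.retained_edges
        assert ("B", "C") in avg.retained_edges


class TestBootstrapAverage:
    def test_frequencies_consistent(self, quad_roles):
        q = simulate_quadruple(ScenarioSpec(seed=8))
        avg = bootstrap_average(q.strain_frame(), quad_roles, n_boot=50, seed=1)
        st = avg.edge_stats
        # direction counts per pair sum to presence count
        for _, row in st.iterrows():
            total = row["dir_ab_freq"] + row["dir_ba_freq"]
            assert total == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= row["presence_freq"] <= 1.0

    def test_deterministic_given_seed(self, quad_roles):
        q = simulate_quadruple(ScenarioSpec(seed=8))
        df = q.strain_frame()
        a = bootstrap_average(df, quad_roles, n_boot=40, seed=9)
        b = bootstrap_average(df, quad_roles, n_boot=40, seed=9)
        pd.testing.assert_frame_equal(a.edge_stats, b.edge_stats)
        assert a.retained_edges == b.retained_edges

    def test_strong_chain_edges_dominate(self, quad_roles):
        q = simulate_quadruple(
            ScenarioSpec(seed=0, effect_sizes={"S->M": 0.9, "M->G": 0.9,
                                               "G->P": -0.9})
        )
        avg = bootstrap_average(q.strain_frame(), quad_roles, n_boot=100, seed=2)
        st = avg.edge_stats.set_index(["node_a", "node_b"])
        for pair in [("M", "S"), ("G", "M"), ("G", "P")]:
            assert st.loc[pair, "presence_freq"] >= 0.85

    def test_pure_noise_retains_little(self, quad_roles):
        # a null dataset whose realized sample correlation for some pair is
        # ~0.23+ (about 40% of datasets at n=60) keeps that edge in most
        # resamples, so zero retention holds in roughly 6 of 10 runs and the
        # per-run spurious count stays small
        zero = 0
        total_retained = 0
        n_runs = 10
        for seed in range(n_runs):
            q = simulate_quadruple(ScenarioSpec(scenario="null", seed=seed))
            avg = bootstrap_average(
                q.strain_frame(), quad_roles, n_boot=60, seed=seed
            )
            zero += len(avg.retained_edges) == 0
            total_retained += len(avg.retained_edges)
        assert zero / n_runs >= 0.5
        assert total_retained / n_runs <= 1.0

    def test_retained_graph_acyclic(self, quad_roles):
        import networkx as nx

        q = simulate_quadruple(ScenarioSpec(seed=14))
        avg = bootstrap_average(q.strain_frame(), quad_roles, n_boot=60, seed=3)
        assert nx.is_directed_acyclic_graph(avg.retained_digraph())
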