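import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mirmediation.bn_core import (
    FamilyScoreCache,
    NetworkStructure,
    NodeRole,
    enumerate_constrained_structures,
    is_mediator,
    node_loglik_binary_root,
    node_loglik_continuous,
    score_network,
    select_best,
)


def brute_force_constrained_dags(roles):
    """Independent oracle: filter ALL directed graphs on the labeled nodes."""
    labels = [r.label for r in roles]
    kind = {r.label: r.kind for r in roles}
    pairs = [(u, v) for u in labels for v in labels if u != v]
    count = 0
    survivors = []
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = {p for p, b in zip(pairs, bits) if b}
        if any(kind[v] == "sdp_binary_root" for _, v in edges):
            continue
        if any(kind[u] == "continuous_phenotype" for u, _ in edges):
            continue
        # acyclicity by repeated sink removal
        nodes = set(labels)
        e = set(edges)
        while True:
            sinks = [n for n in nodes if not any(u == n for u, _ in e)]
            if not sinks:
                break
            nodes -= set(sinks)
            e = {(u, v) for u, v in e if u in nodes and v in nodes}
        if nodes:
            continue
        count += 1
        survivors.append(frozenset(edges))
    return count, survivors


class TestEnumeration:
    def test_quadruple_yields_96(self, quad_roles):
        structures = enumerate_constrained_structures(quad_roles)
        assert len(structures) == 96
        # against the independent brute-force filter of all 4-node digraphs
        count, survivors = brute_force_constrained_dags(quad_roles)
        assert count == 96
        assert {s.edges for s in structures} == set(survivors)

    def test_two_node_yields_2(self):
        roles = [NodeRole("S", "sdp_binary_root"),
                 NodeRole("P", "continuous_phenotype")]
        assert len(enumerate_constrained_structures(roles)) == 2

    def test_three_node_yields_8(self):
        roles = [NodeRole("S", "sdp_binary_root"),
                 NodeRole("M", "continuous_intermediate"),
                 NodeRole("P", "continuous_phenotype")]
        structures = enumerate_constrained_structures(roles)
        count, _ = brute_force_constrained_dags(roles)
        assert len(structures) == count == 8

    def test_structures_unique(self, quad_roles):
        structures = enumerate_constrained_structures(quad_roles)
        assert len({s.edges for s in structures}) == len(structures)

    def test_too_many_nodes_raises(self):
        roles = [NodeRole(f"m{i}", "continuous_intermediate") for i in range(7)]
        with pytest.raises(ValueError, match="hill_climb"):
            enumerate_constrained_structures(roles)


class TestStructureConstraints:
    def test_edge_into_sdp_rejected(self, quad_roles):
        with pytest.raises(ValueError, match="into SDP"):
            NetworkStructure(tuple(quad_roles), frozenset({("M", "S")}))

    def test_edge_out_of_phenotype_rejected(self, quad_roles):
        with pytest.raises(ValueError, match="out of phenotype"):
            NetworkStructure(tuple(quad_roles), frozenset({("P", "M")}))

    def test_cycle_rejected(self, quad_roles):
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure(
                tuple(quad_roles), frozenset({("M", "G"), ("G", "M")})
            )


class TestNodeLoglik:
    def test_no_parent_closed_form(self):
        # values (-1, 1): mean 0, RSS = 2, ML variance = 1
        ll, d, params = node_loglik_continuous(np.array([-1.0, 1.0]), None)
        assert ll == pytest.approx(-(2 / 2) * (math.log(2 * math.pi * 1.0) + 1))
        assert d == 2
        assert params["sigma2"] == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            node_loglik_continuous(np.zeros(4), None)

    def test_singular_design_errors(self, rng):
        y = rng.normal(size=10)
        x = rng.normal(size=10)
        with pytest.raises(np.linalg.LinAlgError):
            node_loglik_continuous(y, np.column_stack([x, 2 * x]))

    def test_matches_numeric_mle(self, rng):
        # independent oracle: direct numeric maximization of the Gaussian
        # regression likelihood
        n = 30
        x = rng.normal(size=(n, 2))
        y = 1.0 + x @ np.array([0.5, -2.0]) + rng.normal(size=n)
        ll, d, _ = node_loglik_continuous(y, x)

        def negll(theta):
            b0, b1, b2, log_s2 = theta
            resid = y - b0 - x @ np.array([b1, b2])
            s2 = np.exp(log_s2)
            return 0.5 * n * np.log(2 * np.pi * s2) + 0.5 * resid @ resid / s2

        res = optimize.minimize(negll, [0, 0, 0, 0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert ll == pytest.approx(-res.fun, abs=1e-6)
        assert d == 4

    @pytest.mark.parametrize(
        "values,expected",
        [
            (np.ones(6), 0.0),
            (np.array([1] * 5 + [0] * 5), 10 * math.log(0.5)),
            (np.array([1] * 3 + [0] * 7), 3 * math.log(0.3) + 7 * math.log(0.7)),
        ],
    )
    def test_binary_root_closed_forms(self, values, expected):
        ll, d, p_hat = node_loglik_binary_root(values)
        assert ll == pytest.approx(expected)
        assert d == 1


class TestScoring:
    def _data(self, rng, n=40):
        s = rng.binomial(1, 0.5, n).astype(float)
        m = 0.8 * s + rng.normal(size=n)
        g = 0.7 * m + rng.normal(size=n)
        p = -0.5 * g + rng.normal(size=n)
        return pd.DataFrame({"S": s, "M": m, "G": g, "P": p})

    def test_empty_network_closed_form(self, quad_roles, rng):
        data = self._data(rng)
        n = len(data)
        structure = NetworkStructure(tuple(quad_roles), frozenset())
        sc = score_network(structure, data)
        expected_ll = 0.0
        p_hat = data["S"].mean()
        expected_ll += n * (p_hat * math.log(p_hat) + (1 - p_hat) * math.log(1 - p_hat))
        for c in ["M", "G", "P"]:
            s2 = data[c].var(ddof=0)
            expected_ll += -0.5 * n * (math.log(2 * math.pi * s2) + 1)
        d = 1 + 3 * 2
        assert sc.loglik == pytest.approx(expected_ll, abs=1e-8)
        assert sc.d == d
        assert sc.bic == pytest.approx(expected_ll - d / 2 * math.log(n), abs=1e-8)

    def test_adding_edge_never_decreases_loglik(self, quad_roles, rng):
        data = self._data(rng)
        base = NetworkStructure(tuple(quad_roles), frozenset({("M", "G")}))
        bigger = NetworkStructure(
            tuple(quad_roles), frozenset({("M", "G"), ("S", "G")})
        )
        assert score_network(bigger, data).loglik >= score_network(base, data).loglik

    def test_decomposability_matches_cache(self, quad_roles, rng):
        data = self._data(rng)
        cache = FamilyScoreCache(data, {r.label: r.kind for r in quad_roles})
        for structure in enumerate_constrained_structures(quad_roles)[:20]:
            direct = score_network(structure, data)
            cached = cache.score(structure)
            assert cached.bic == pytest.approx(direct.bic, abs=1e-10)

    def test_invariant_to_strain_order(self, quad_roles, rng):
        data = self._data(rng)
        structure = NetworkStructure(
            tuple(quad_roles), frozenset({("S", "M"), ("M", "G"), ("G", "P")})
        )
        shuffled = data.sample(frac=1.0, random_state=0)
        assert score_network(structure, data).bic == pytest.approx(
            score_network(structure, shuffled).bic, abs=1e-9
        )

    def test_markov_equivalent_orientations_score_equally(self, quad_roles, rng):
        # S->M, S->G plus M->G vs G->M with compensating parents: same
        # likelihood-equivalence class, identical d, equal BIC
        data = self._data(rng)
        a = NetworkStructure(
            tuple(quad_roles),
            frozenset({("S", "M"), ("S", "G"), ("M", "G"), ("G", "P")}),
        )
        b = NetworkStructure(
            tuple(quad_roles),
            frozenset({("S", "M"), ("S", "G"), ("G", "M"), ("G", "P")}),
        )
        sa, sb = score_network(a, data), score_network(b, data)
        assert sa.d == sb.d
        assert sa.bic == pytest.approx(sb.bic, abs=1e-7)

    def test_spurious_parent_penalized(self, quad_roles):
        # a true-zero-effect parent should lower BIC for most datasets
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            r = np.random.default_rng(seed)
            n = 40
            data = pd.DataFrame(
                {
                    "S": r.binomial(1, 0.5, n).astype(float),
                    "M": r.normal(size=n),
                    "G": r.normal(size=n),
                    "P": r.normal(size=n),
                }
            )
            base = NetworkStructure(tuple(quad_roles), frozenset())
            plus = NetworkStructure(tuple(quad_roles), frozenset({("M", "G")}))
            hits += score_network(plus, data).bic < score_network(base, data).bic
        assert hits / n_trials >= 0.9


class TestMediator:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ({("S", "M"), ("M", "P")}, True),
            ({("S", "P")}, False),
            ({("S", "M"), ("M", "G"), ("G", "P"), ("S", "P")}, True),
            ({("S", "M"), ("S", "G"), ("G", "M"), ("G", "P")}, False),
        ],
    )
    def test_path_membership(self, quad_roles, edges, expected):
        structure = NetworkStructure(tuple(quad_roles), frozenset(edges))
        assert is_mediator(structure, "S", "M", "P") is expected

    def test_agrees_with_path_enumeration(self, quad_roles):
        # brute-force: enumerate all simple paths S -> P, check membership
        import networkx as nx

        for structure in enumerate_constrained_structures(quad_roles):
            g = structure.to_digraph()
            paths = list(nx.all_simple_paths(g, "S", "P"))
            oracle = any("M" in p[1:-1] for p in paths)
            assert is_mediator(structure, "S", "M", "P") == oracle


class TestSelection:
    def test_tie_prefers_fewer_edges(self, quad_roles, rng):
        data = self._mkdata(rng)
        cache = FamilyScoreCache(data, {r.label: r.kind for r in quad_roles})
        a = cache.score(NetworkStructure(tuple(quad_roles), frozenset()))
        b = cache.score(
            NetworkStructure(tuple(quad_roles), frozenset({("M", "G")}))
        )
        b.loglik = a.loglik + (b.d - a.d) / 2 * math.log(cache.n)  # force tie
        assert select_best([b, a]).structure.edges == frozenset()

    @staticmethod
    def _mkdata(rng, n=30):
        return pd.DataFrame(
            {
                "S": rng.binomial(1, 0.5, n).astype(float),
                "M": rng.normal(size=n),
                "G": rng.normal(size=n),
                "P": rng.normal(size=n),
            }
        )
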