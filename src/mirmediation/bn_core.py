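"""Constrained hybrid Gaussian Bayesian networks and their BIC score.

The model class is a hybrid Bayesian network over typed nodes: binary
genetic markers (SDPs) that act as causal anchors, and continuous
miRNA-expression, gene-expression and phenotype nodes. Two role constraints
are enforced on every structure, justified by Mendelian randomization and by
the phenotype being a terminal response:

* every edge incident to an SDP node points away from the SDP;
* every edge incident to a phenotype node points into the phenotype.

Because binary nodes are never children, each continuous node follows a
linear-Gaussian conditional (OLS of the child on its parents) and each
binary root contributes only its unconditional Bernoulli density, so the
joint log-likelihood decomposes over node families.

Structures are compared by the score

    BIC = log L_hat - (d / 2) * log(n)

with natural logarithms, n the number of strains and d the total parameter
count (parents + 2 per continuous node: intercept, slopes, ML residual
variance; 1 per binary root). Higher BIC indicates greater support.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeRole",
    "NetworkStructure",
    "ScoredNetwork",
    "FamilyScoreCache",
    "enumerate_constrained_structures",
    "node_loglik_continuous",
    "node_loglik_binary_root",
    "score_network",
    "is_mediator",
    "select_best",
    "allowed_arcs",
]

KINDS = ("sdp_binary_root", "continuous_intermediate", "continuous_phenotype")


@dataclass(frozen=True)
class NodeRole:
    label: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkStructure:
    """A DAG over typed nodes satisfying the role constraints."""

    nodes: tuple[NodeRole, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        kind = {r.label: r.kind for r in self.nodes}
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if u not in kind or v not in kind:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            if kind[v] == "sdp_binary_root":
                raise ValueError(f"edge into SDP node {v}")
            if kind[u] == "continuous_phenotype":
                raise ValueError(f"edge out of phenotype node {u}")
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise ValueError("structure contains a cycle")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(r.label for r in self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, label: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == label))

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def role(self, label: str) -> NodeRole:
        for r in self.nodes:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class ScoredNetwork:
    structure: NetworkStructure
    loglik: float
    d: int
    n: int
    node_params: dict = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return self.loglik - 0.5 * self.d * math.log(self.n)


def allowed_arcs(nodes: tuple[NodeRole, ...] | list[NodeRole]) -> list[tuple[str, str]]:
    """All single arcs permitted by the role constraints (ignoring acyclicity)."""
    kind = {r.label: r.kind for r in nodes}
    return [
        (u, v)
        for u in kind
        for v in kind
        if u != v
        and kind[v] != "sdp_binary_root"
        and kind[u] != "continuous_phenotype"
    ]


def enumerate_constrained_structures(
    nodes: list[NodeRole] | tuple[NodeRole, ...],
    max_nodes: int = 6,
) -> list[NetworkStructure]:
    """Enumerate every admissible DAG on the given typed nodes, each exactly once.

    Cycles can only form among the continuous intermediate nodes (SDP nodes
    have no incoming, phenotype nodes no outgoing edges), so the enumeration
    factors: all DAGs on the intermediates, crossed with every subset of the
    remaining "free" arcs (SDP -> anything, intermediate -> phenotype). For
    one SDP, one miRNA, one gene and one phenotype this yields 96 structures.
    """
    nodes = tuple(nodes)
    if len(nodes) > max_nodes:
        raise ValueError(
            f"{len(nodes)} nodes exceeds the exhaustive-enumeration limit "
            f"({max_nodes}); use hill_climb for larger node sets"
        )
    mids = [r.label for r in nodes if r.kind == "continuous_intermediate"]
    mid_arcs = [(u, v) for u in mids for v in mids if u != v]
    free_arcs = [a for a in allowed_arcs(nodes) if a not in set(mid_arcs)]

    mid_dags: list[frozenset] = []
    for r in range(len(mid_arcs) + 1):
        for subset in itertools.combinations(mid_arcs, r):
            g = nx.DiGraph(subset)
            if nx.is_directed_acyclic_graph(g):
                mid_dags.append(frozenset(subset))

    structures = []
    for dag in mid_dags:
        for r in range(len(free_arcs) + 1):
            for fsub in itertools.combinations(free_arcs, r):
                structures.append(NetworkStructure(nodes, dag | frozenset(fsub)))
    return structures


def node_loglik_continuous(
    child: np.ndarray, parents: np.ndarray | None
) -> tuple[float, int, dict]:
    """Maximized Gaussian log-likelihood of a continuous node given its parents.

    OLS of the child on an intercept plus the parent columns; the residual
    variance is the maximum-likelihood estimate RSS/n (not RSS/(n-k)), so the
    returned value is the true maximized log-likelihood entering the BIC.

    Returns (loglik, parameter count = n_parents + 2, fitted params).
    """
    y = np.asarray(child, dtype=float)
    n = y.shape[0]
    if parents is None or parents.size == 0:
        k = 0
        design = np.ones((n, 1))
    else:
        x = np.asarray(parents, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        k = x.shape[1]
        design = np.column_stack([np.ones(n), x])
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} parents")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design (collinear parents)")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    if rss <= n * 1e-12:
        raise ValueError("zero residual variance (degenerate node data)")
    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    params = {
        "intercept": float(beta[0]),
        "coefficients": [float(b) for b in beta[1:]],
        "sigma2": sigma2,
    }
    return loglik, k + 2, params


def node_loglik_binary_root(values: np.ndarray) -> tuple[float, int, float]:
    """Bernoulli log-likelihood of a binary root node (0*log 0 taken as 0)."""
    v = np.asarray(values, dtype=float)
    if not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("binary root values must be 0/1")
    n = v.shape[0]
    ones = float(v.sum())
    p_hat = ones / n
    loglik = 0.0
    if 0 < p_hat:
        loglik += ones * math.log(p_hat)
    if p_hat < 1:
        loglik += (n - ones) * math.log(1.0 - p_hat)
    return loglik, 1, p_hat


class FamilyScoreCache:
    """Per-family (child, parent-set) score cache over a fixed data matrix.

    The BIC is decomposable, so enumeration and local search only ever need
    family scores; caching them makes exhaustive 96-structure scans and
    bootstrap hill-climbing cheap.
    """

    def __init__(self, data: pd.DataFrame, kinds: dict[str, str]):
        self._cols = {c: data[c].to_numpy(dtype=float) for c in data.columns}
        self._kinds = kinds
        self._cache: dict[tuple, tuple[float, int, object]] = {}
        self.n = len(data)

    def family(self, child: str, parents: tuple[str, ...]) -> tuple[float, int, object]:
        """Family score; degenerate families (collinear parents, zero residual
        variance) score -inf so structure search simply avoids them."""
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            kind = self._kinds[child]
            try:
                if kind == "sdp_binary_root":
                    if parents:
                        raise ValueError("binary root cannot have parents")
                    self._cache[key] = node_loglik_binary_root(self._cols[child])
                else:
                    pmat = (
                        np.column_stack([self._cols[p] for p in key[1]])
                        if parents
                        else None
                    )
                    self._cache[key] = node_loglik_continuous(
                        self._cols[child], pmat
                    )
            except (np.linalg.LinAlgError, ValueError):
                self._cache[key] = (-math.inf, len(parents) + 2, None)
        return self._cache[key]

    def score(self, structure: NetworkStructure) -> ScoredNetwork:
        loglik = 0.0
        d = 0
        params = {}
        for role in structure.nodes:
            ll, dk, pk = self.family(role.label, structure.parents(role.label))
            loglik += ll
            d += dk
            params[role.label] = pk
        return ScoredNetwork(structure=structure, loglik=loglik, d=d, n=self.n,
                             node_params=params)


def score_network(structure: NetworkStructure, data: pd.DataFrame) -> ScoredNetwork:
    """Score one structure on aligned strain data (columns = node labels).

    Unlike cache-mediated search, degenerate node data raise here.
    """
    kinds = {r.label: r.kind for r in structure.nodes}
    sc = FamilyScoreCache(data[[r.label for r in structure.nodes]], kinds).score(
        structure
    )
    if not math.isfinite(sc.loglik):
        raise ValueError(
            "degenerate node data (zero variance or collinear parents)"
        )
    return sc


def is_mediator(
    structure: NetworkStructure, source: str, via: str, sink: str
) -> bool:
    """True iff some directed path from ``source`` to ``sink`` passes through ``via``."""
    g = structure.to_digraph()
    for lab in (source, via, sink):
        if lab not in g:
            raise KeyError(lab)
    return nx.has_path(g, source, via) and nx.has_path(g, via, sink)


def select_best(scored: list[ScoredNetwork]) -> ScoredNetwork:
    """Highest-BIC network; exact ties prefer fewer edges, then lexicographic edges."""
    if not scored:
        raise ValueError("no scored networks to select from")
    best = scored[0]
    for cand in scored[1:]:
        if cand.bic > best.bic:
            best = cand
        elif cand.bic == best.bic:
            ckey = (len(cand.structure.edges), cand.structure.sorted_edges())
            bkey = (len(best.structure.edges), best.structure.sorted_edges())
            if ckey < bkey:
                best = cand
    return best
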