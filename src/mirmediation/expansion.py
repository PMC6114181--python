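"""Locus-window grouping and bootstrap-averaged structure learning.

Quadruples that pass the mediation screen and share a phenotype are merged
when their SDPs sit on the same chromosome within a linkage window (default
40 Mb, single-linkage chaining on SDP-span midpoints): physically close
markers are usually in high LD and their separate hits likely reflect one
underlying locus. Each merged node set is then re-learned as a single
network by score-based search — exhaustively when the node set is small,
otherwise by greedy hill-climbing over single-edge additions, deletions and
reversals that respect the role constraints.

Stability is assessed by nonparametric bootstrap over strains (the
exchangeable sampling unit): the structure search is repeated on each
resample and edges are averaged across replicates. An edge and a direction
are retained only when each appears in more than half of the replicates
(strict > 50%); nodes left without any retained edge are dropped from the
final network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bn_core import (
    FamilyScoreCache,
    NetworkStructure,
    NodeRole,
    ScoredNetwork,
    allowed_arcs,
    enumerate_constrained_structures,
    select_best,
)
from .data_io import AlignedDataset, SDPTable
from .mediation import MediationDecision

logger = logging.getLogger("mirmediation")

__all__ = [
    "LocusGroup",
    "AveragedNetwork",
    "group_by_locus",
    "hill_climb",
    "bootstrap_average",
    "group_dataset",
    "apply_retention",
]

LOCUS_WINDOW_BP_DEFAULT = 40_000_000
N_BOOT_DEFAULT = 500
RETENTION_DEFAULT = 0.5
EXHAUSTIVE_IF_SMALL_DEFAULT = 5


@dataclass
class LocusGroup:
    """Nodes pooled across mediation-passing quadruples at one locus."""

    phenotype_id: str
    sdp_ids: list[str]
    mirna_ids: list[str]
    gene_ids: list[str]

    def node_count(self) -> int:
        return len(self.sdp_ids) + len(self.mirna_ids) + len(self.gene_ids) + 1


@dataclass
class AveragedNetwork:
    """Bootstrap edge/direction frequencies with the >50% retention rule applied."""

    nodes: list[str]
    edge_stats: pd.DataFrame  # node_a < node_b; presence/direction frequencies
    retained_edges: list[tuple[str, str]]
    dropped_nodes: list[str]
    n_boot: int

    def retained_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n for n in self.nodes if n not in self.dropped_nodes)
        g.add_edges_from(self.retained_edges)
        return g

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the retained network, edges labelled
        with their bootstrap presence frequency."""
        freq = {
            tuple(sorted((r["node_a"], r["node_b"]))): r["presence_freq"]
            for _, r in self.edge_stats.iterrows()
        }
        lines = ["digraph averaged {"]
        for n in self.nodes:
            if n not in self.dropped_nodes:
                lines.append(f'  "{n}";')
        for u, v in self.retained_edges:
            f = freq.get(tuple(sorted((u, v))), 0.0)
            lines.append(f'  "{u}" -> "{v}" [label="{f:.2f}"];')
        lines.append("}")
        return "\n".join(lines)


def group_by_locus(
    decisions: list[MediationDecision],
    sdp_table: SDPTable,
    window_bp: int = LOCUS_WINDOW_BP_DEFAULT,
) -> list[LocusGroup]:
    """Cluster passing quadruples per phenotype by SDP proximity.

    SDP positions are the midpoints of their member-SNP spans on their
    assigned chromosome; clustering is single-linkage, so a chain of gaps
    each within the window merges into one group even when its extremes are
    farther apart.
    """
    passing = [d for d in decisions if d.mediation_pass]
    groups: list[LocusGroup] = []
    by_pheno: dict[str, list[MediationDecision]] = {}
    for d in passing:
        by_pheno.setdefault(d.phenotype_id, []).append(d)

    for pheno in sorted(by_pheno):
        decs = by_pheno[pheno]
        # one entry per distinct SDP, with all its decisions
        per_sdp: dict[str, list[MediationDecision]] = {}
        for d in decs:
            per_sdp.setdefault(d.sdp_id, []).append(d)
        located = [
            (sdp_table.midpoint(s)[0], sdp_table.midpoint(s)[1], s)
            for s in per_sdp
        ]
        for chrom in sorted({c for c, _, _ in located}, key=str):
            on_chrom = sorted(
                [(mid, s) for c, mid, s in located if c == chrom]
            )
            cluster: list[str] = []
            prev_mid = None
            for mid, sdp in on_chrom:
                if prev_mid is not None and mid - prev_mid > window_bp:
                    groups.append(_make_group(pheno, cluster, per_sdp))
                    cluster = []
                cluster.append(sdp)
                prev_mid = mid
            if cluster:
                groups.append(_make_group(pheno, cluster, per_sdp))
    return groups


def _make_group(
    pheno: str, sdp_ids: list[str], per_sdp: dict[str, list[MediationDecision]]
) -> LocusGroup:
    mirnas: set[str] = set()
    genes: set[str] = set()
    for s in sdp_ids:
        for d in per_sdp[s]:
            mirnas.add(d.mirna_id)
            if d.gene_pass:
                genes.add(d.gene_id)
    return LocusGroup(
        phenotype_id=pheno,
        sdp_ids=sorted(sdp_ids),
        mirna_ids=sorted(mirnas),
        gene_ids=sorted(genes),
    )


def group_dataset(
    group: LocusGroup, dataset: AlignedDataset
) -> tuple[pd.DataFrame, list[NodeRole]]:
    """Assemble the strain x node data frame and roles for one locus group."""
    cols: dict[str, np.ndarray] = {}
    roles: list[NodeRole] = []
    for s in group.sdp_ids:
        cols[s] = dataset.sdp_vector(s)
        roles.append(NodeRole(s, "sdp_binary_root"))
    for m in group.mirna_ids:
        cols[m] = dataset.mirna[m].to_numpy(dtype=float)
        roles.append(NodeRole(m, "continuous_intermediate"))
    for g in group.gene_ids:
        cols[g] = dataset.genes[g].to_numpy(dtype=float)
        roles.append(NodeRole(g, "continuous_intermediate"))
    pid = str(dataset.phenotype.name)
    cols[pid] = dataset.phenotype.to_numpy(dtype=float)
    roles.append(NodeRole(pid, "continuous_phenotype"))
    return pd.DataFrame(cols, index=dataset.strain_ids), roles


# ---------------------------------------------------------------------------
# Greedy structure search
# ---------------------------------------------------------------------------

def hill_climb(
    data: pd.DataFrame,
    roles: list[NodeRole],
    start: NetworkStructure | None = None,
    max_iter: int = 200,
    cache: FamilyScoreCache | None = None,
) -> ScoredNetwork:
    """Greedy BIC hill-climbing over single-edge moves.

    Moves are arc additions, deletions and reversals that respect the role
    constraints and acyclicity; a move is accepted only when it strictly
    improves the BIC, taking the best improvement each round. Ties among
    equal improvements prefer additions over reversals over deletions, then
    the lexicographically smallest arc — the search is fully deterministic.
    At a single-move local optimum, score-neutral reversals (covered-edge
    flips within a Markov equivalence class) are probed one step ahead and
    accepted when they unlock a strictly improving follow-up move.
    The returned network carries a ``converged`` attribute, False when
    ``max_iter`` rounds were exhausted before reaching a local optimum.
    """
    nodes = tuple(roles)
    labels = [r.label for r in nodes]
    if cache is None:
        cache = FamilyScoreCache(data[labels], {r.label: r.kind for r in nodes})
    arcs = allowed_arcs(nodes)
    current = start if start is not None else NetworkStructure(nodes, frozenset())

    converged = False
    for _ in range(max_iter):
        candidates = _enumerate_moves(current, arcs, cache)
        improving = [c for c in candidates if c[3] > 0.0]
        if not improving:
            # Local optimum under single moves. Score-equivalent reversals
            # (delta == 0 up to rounding) flip covered edges between Markov-
            # equivalent structures; if one of them unlocks a strictly
            # improving move, take the pair. This escapes the classic trap
            # where a tie-broken early edge orientation freezes the search
            # one equivalence-class step away from the optimum.
            escape = None
            neutral = sorted(
                (c for c in candidates if c[0] == 1 and abs(c[3]) <= 1e-9),
                key=lambda c: c[1],
            )
            for _, arc, new_edges, delta0 in neutral:
                trial = NetworkStructure(nodes, new_edges)
                followups = [
                    c for c in _enumerate_moves(trial, arcs, cache)
                    if delta0 + c[3] > 1e-9
                ]
                if followups:
                    best_gain = max(c[3] for c in followups)
                    nxt = min(
                        (c for c in followups if c[3] == best_gain),
                        key=lambda c: (c[0], c[1]),
                    )
                    escape = NetworkStructure(nodes, nxt[2])
                    break
            if escape is None:
                converged = True
                break
            current = escape
            continue
        best_delta = max(c[3] for c in improving)
        best_move = min(
            (c for c in improving if c[3] == best_delta),
            key=lambda c: (c[0], c[1]),
        )
        current = NetworkStructure(nodes, best_move[2])
    cur_score = cache.score(current)
    cur_score.converged = converged
    return cur_score


def _enumerate_moves(
    current: NetworkStructure,
    arcs: list[tuple[str, str]],
    cache: FamilyScoreCache,
) -> list[tuple[int, tuple[str, str], frozenset, float]]:
    """All admissible single-edge moves as (priority, arc, edges, delta-BIC).

    Priority encodes the tie order: 0 additions, 1 reversals, 2 deletions.
    Deltas touch only the affected families (BIC decomposability).
    """
    edges = current.edges
    nodes = current.nodes
    g = current.to_digraph()
    arc_set = set(arcs)

    def family_bic(child: str, parents: tuple[str, ...]) -> float:
        ll, d, _ = cache.family(child, parents)
        return ll - 0.5 * d * np.log(cache.n)

    def parents_of(child: str, edge_set: frozenset) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in edge_set if v == child))

    candidates: list[tuple[int, tuple[str, str], frozenset, float]] = []
    for u, v in arcs:
        if (u, v) in edges or (v, u) in edges:
            continue  # present, or handled as a reversal
        if nx.has_path(g, v, u):
            continue  # would close a cycle
        new_edges = edges | {(u, v)}
        delta = family_bic(v, parents_of(v, new_edges)) - family_bic(
            v, parents_of(v, edges)
        )
        candidates.append((0, (u, v), new_edges, delta))
    for u, v in sorted(edges):
        if (v, u) in arc_set:
            g2 = g.copy()
            g2.remove_edge(u, v)
            if not nx.has_path(g2, u, v):
                new_edges = (edges - {(u, v)}) | {(v, u)}
                delta = (
                    family_bic(v, parents_of(v, new_edges))
                    - family_bic(v, parents_of(v, edges))
                    + family_bic(u, parents_of(u, new_edges))
                    - family_bic(u, parents_of(u, edges))
                )
                candidates.append((1, (v, u), new_edges, delta))
    for u, v in sorted(edges):
        new_edges = edges - {(u, v)}
        delta = family_bic(v, parents_of(v, new_edges)) - family_bic(
            v, parents_of(v, edges)
        )
        candidates.append((2, (u, v), new_edges, delta))
    return candidates


# ---------------------------------------------------------------------------
# Bootstrap model averaging
# ---------------------------------------------------------------------------

def bootstrap_average(
    data: pd.DataFrame,
    roles: list[NodeRole],
    n_boot: int = N_BOOT_DEFAULT,
    retention: float = RETENTION_DEFAULT,
    seed: int = 0,
    direction_denominator: str = "edge_present",
    exhaustive_if_small: int = EXHAUSTIVE_IF_SMALL_DEFAULT,
    max_iter: int = 200,
) -> AveragedNetwork:
    """Learn a structure on each strain resample and average the edges.

    Each bootstrap draws ``n`` strains with replacement; a replicate in which
    some node has zero variance (e.g. a marker resampled to one allele) is
    redrawn, up to 10 attempts. Node sets of at most ``exhaustive_if_small``
    nodes are learned by exhaustive constrained enumeration, larger ones by
    :func:`hill_climb` from the empty structure. Direction frequencies are,
    by default, conditional on the edge being present in a replicate
    (``direction_denominator="edge_present"``); ``"all_bootstraps"`` divides
    by the replicate count instead. Retention requires presence frequency
    > ``retention`` and winning-direction frequency > ``retention``; if the
    retained edges would form a cycle they are admitted in decreasing
    presence frequency, skipping (and logging) any cycle-closing edge.
    """
    if direction_denominator not in ("edge_present", "all_bootstraps"):
        raise ValueError("direction_denominator must be edge_present|all_bootstraps")
    nodes = tuple(roles)
    labels = [r.label for r in nodes]
    kinds = {r.label: r.kind for r in nodes}
    n = len(data)
    if n < 6:
        raise ValueError(f"n={n} too small for bootstrap averaging")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    structures = (
        enumerate_constrained_structures(list(nodes))
        if len(nodes) <= exhaustive_if_small
        else None
    )

    pair_count: dict[tuple[str, str], int] = {}
    dir_count: dict[tuple[str, str], int] = {}
    mat = data[labels]
    for _ in range(n_boot):
        sample = None
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            cand = mat.iloc[idx].reset_index(drop=True)
            if all(np.ptp(cand[c].to_numpy(dtype=float)) > 0 for c in labels):
                sample = cand
                break
            logger.debug("degenerate bootstrap replicate redrawn (attempt %d)",
                         attempt + 1)
        if sample is None:
            raise RuntimeError(
                "could not draw a non-degenerate bootstrap replicate in 10 tries"
            )
        cache = FamilyScoreCache(sample, kinds)
        if structures is not None:
            best = select_best([cache.score(s) for s in structures])
        else:
            best = hill_climb(sample, list(nodes), cache=cache, max_iter=max_iter)
        for u, v in best.structure.edges:
            key = (u, v) if u < v else (v, u)
            pair_count[key] = pair_count.get(key, 0) + 1
            dir_count[(u, v)] = dir_count.get((u, v), 0) + 1

    return apply_retention(
        pair_count, dir_count, labels, n_boot,
        retention=retention, direction_denominator=direction_denominator,
    )


def apply_retention(
    pair_count: dict[tuple[str, str], int],
    dir_count: dict[tuple[str, str], int],
    labels: list[str],
    n_boot: int,
    retention: float = RETENTION_DEFAULT,
    direction_denominator: str = "edge_present",
) -> AveragedNetwork:
    """Apply the strict >retention presence and direction rules to edge tallies.

    ``pair_count`` keys are sorted undirected pairs; ``dir_count`` keys are
    directed. An edge present in exactly half the replicates is *not*
    retained. If the surviving edges would close a cycle, they are admitted
    in decreasing presence frequency and the cycle-closing edge is skipped.
    """
    rows = []
    retained_candidates = []
    for a, b in sorted(pair_count):
        presence = pair_count[(a, b)]
        ab = dir_count.get((a, b), 0)
        ba = dir_count.get((b, a), 0)
        presence_freq = presence / n_boot
        denom = presence if direction_denominator == "edge_present" else n_boot
        f_ab = ab / denom
        f_ba = ba / denom
        rows.append(
            {
                "node_a": a, "node_b": b,
                "presence_freq": presence_freq,
                "dir_ab_freq": f_ab, "dir_ba_freq": f_ba,
                "n_present": presence,
            }
        )
        if presence_freq > retention:
            if f_ab > retention and f_ab > f_ba:
                retained_candidates.append((presence_freq, f_ab, (a, b)))
            elif f_ba > retention and f_ba > f_ab:
                retained_candidates.append((presence_freq, f_ba, (b, a)))

    # admit by decreasing presence frequency, skipping cycle-closing edges
    retained: list[tuple[str, str]] = []
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for pf, df_, (u, v) in sorted(
        retained_candidates, key=lambda t: (-t[0], -t[1], t[2])
    ):
        if nx.has_path(g, v, u):
            logger.warning("edge %s->%s skipped: would close a cycle", u, v)
            continue
        g.add_edge(u, v)
        retained.append((u, v))

    connected = {u for e in retained for u in e}
    dropped = [l for l in labels if l not in connected]
    stats = pd.DataFrame(
        rows,
        columns=["node_a", "node_b", "presence_freq", "dir_ab_freq",
                 "dir_ba_freq", "n_present"],
    )
    return AveragedNetwork(
        nodes=labels,
        edge_stats=stats,
        retained_edges=sorted(retained),
        dropped_nodes=dropped,
        n_boot=n_boot,
    )
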