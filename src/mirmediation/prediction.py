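"""Interventional phenotype-change prediction on a fitted network.

Once a final structure is fixed, each continuous node is refit by OLS on its
parents and the network becomes a linear structural-equation model. The
predicted phenotype change for increasing a miRNA or gene node is computed
under do-style intervention semantics: the target is *set* (not observed),
so the change propagates only through the target's descendants and never
back to the genetic anchor. For a linear system the effect is

    delta_phenotype = delta_input * sum over directed paths
                      (target -> ... -> phenotype) of the product of the
                      edge coefficients along the path,

and the implementation computes the change both ways — forward propagation
of expected values and the path-coefficient sum — and cross-checks them.

The intervention spans mirror reporting on observed expression ranges:
``two_quartile`` moves the target from its first to its third quartile and
``four_quartile`` from its minimum to its maximum, quartiles taken from the
training strains (linear-interpolation convention by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bn_core import (
    FamilyScoreCache,
    NetworkStructure,
)

__all__ = ["FittedNetwork", "InterventionResult", "fit_network_parameters",
           "predict_phenotype_change", "plot_intervention_bars"]

CROSS_CHECK_TOL = 1e-10


@dataclass
class FittedNetwork:
    structure: NetworkStructure
    node_params: dict[str, dict]      # continuous: intercept/coefficients/sigma2
    root_probs: dict[str, float]      # binary roots: success probability
    quantiles: pd.DataFrame           # nodes x [min, q1, q3, max]
    n: int

    def coefficient(self, parent: str, child: str) -> float:
        params = self.node_params[child]
        parents = self.structure.parents(child)
        return params["coefficients"][parents.index(parent)]


@dataclass
class InterventionResult:
    target_node: str
    span: str                      # two_quartile | four_quartile
    delta_input: float
    delta_phenotype: float
    path_decomposition: dict[tuple[str, ...], float]


def fit_network_parameters(
    structure: NetworkStructure,
    data: pd.DataFrame,
    quantile_method: str = "linear",
) -> FittedNetwork:
    """OLS-fit every node family and record per-node training quantiles."""
    kinds = {r.label: r.kind for r in structure.nodes}
    labels = list(kinds)
    cache = FamilyScoreCache(data[labels], kinds)
    node_params: dict[str, dict] = {}
    root_probs: dict[str, float] = {}
    for role in structure.nodes:
        _, _, params = cache.family(role.label, structure.parents(role.label))
        if role.kind == "sdp_binary_root":
            root_probs[role.label] = params
        else:
            node_params[role.label] = params
    qs = {}
    for lab in labels:
        v = data[lab].to_numpy(dtype=float)
        qs[lab] = [
            float(v.min()),
            float(np.quantile(v, 0.25, method=quantile_method)),
            float(np.quantile(v, 0.75, method=quantile_method)),
            float(v.max()),
        ]
    quantiles = pd.DataFrame(qs, index=["min", "q1", "q3", "max"]).T
    return FittedNetwork(
        structure=structure,
        node_params=node_params,
        root_probs=root_probs,
        quantiles=quantiles,
        n=len(data),
    )


def _propagated_delta(fitted: FittedNetwork, target: str, delta: float) -> float:
    """Forward-propagate an additive shift of the target through descendants."""
    g = fitted.structure.to_digraph()
    shift = {target: delta}
    for node in nx.topological_sort(g):
        if node == target or node not in fitted.node_params:
            continue
        parents = fitted.structure.parents(node)
        if not parents:
            continue
        coefs = fitted.node_params[node]["coefficients"]
        s = sum(
            coefs[i] * shift.get(p, 0.0) for i, p in enumerate(parents)
        )
        if s != 0.0:
            shift[node] = s
    pheno = next(
        r.label for r in fitted.structure.nodes if r.kind == "continuous_phenotype"
    )
    return shift.get(pheno, 0.0)


def predict_phenotype_change(
    fitted: FittedNetwork, target_node: str, span: str = "two_quartile"
) -> InterventionResult:
    """Predicted phenotype change when the target is raised across its span.

    Raises if the target is the phenotype or a genetic (SDP) node — only
    expression nodes are meaningful intervention targets.
    """
    role = fitted.structure.role(target_node)
    if role.kind != "continuous_intermediate":
        raise ValueError(
            f"intervention target must be a miRNA/gene node, not {role.kind}"
        )
    if span not in ("two_quartile", "four_quartile"):
        raise ValueError("span must be 'two_quartile' or 'four_quartile'")
    q = fitted.quantiles.loc[target_node]
    delta_input = float(
        q["q3"] - q["q1"] if span == "two_quartile" else q["max"] - q["min"]
    )

    pheno = next(
        r.label for r in fitted.structure.nodes if r.kind == "continuous_phenotype"
    )
    g = fitted.structure.to_digraph()
    decomposition: dict[tuple[str, ...], float] = {}
    total_path = 0.0
    if nx.has_path(g, target_node, pheno):
        for path in nx.all_simple_paths(g, target_node, pheno):
            prod = 1.0
            for u, v in zip(path[:-1], path[1:]):
                prod *= fitted.coefficient(u, v)
            decomposition[tuple(path)] = prod
            total_path += prod
    delta_paths = delta_input * total_path
    delta_prop = _propagated_delta(fitted, target_node, delta_input)
    if abs(delta_paths - delta_prop) > CROSS_CHECK_TOL * max(
        1.0, abs(delta_paths), abs(delta_prop)
    ):
        raise AssertionError(
            f"path-product ({delta_paths}) and propagation ({delta_prop}) disagree"
        )
    return InterventionResult(
        target_node=target_node,
        span=span,
        delta_input=delta_input,
        delta_phenotype=delta_paths,
        path_decomposition=decomposition,
    )


def plot_intervention_bars(results: list[InterventionResult], path):
    """Bar chart of predicted phenotype changes, one bar per (target, span)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r.target_node}\n{r.span.replace('_', '-')}" for r in results]
    deltas = [r.delta_phenotype for r in results]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(results), 3.5))
    colors = ["#4477aa" if d >= 0 else "#cc6677" for d in deltas]
    ax.bar(range(len(deltas)), deltas, color=colors)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(labels)), labels, fontsize=8)
    ax.set_ylabel("predicted phenotype change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
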