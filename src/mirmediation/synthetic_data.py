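"""Synthetic RI-panel data with known causal wiring.

Generates the three ingredients of the analysis under a controlled truth:

* **Genotypes** — recombinant-inbred strains are mosaics of two parental
  genomes; allele origin along each chromosome follows a two-state Markov
  chain, so nearby SNPs are in strong LD and collapse into strain
  distribution patterns (SDPs).
* **Expression** — miRNA and gene values are produced at the biological
  replicate level (strain-level signal plus replicate noise) on a Gaussian
  scale, matching variance-stabilized / log2 data.
* **Causal quadruples** — linear-Gaussian structural equations over
  SDP -> miRNA -> gene -> phenotype wirings in configurable scenarios
  (full mediation, mediation without the gene, direct-only, null, and a
  reverse gene -> miRNA variant), with the SDP entering as a 0/1 covariate.

Effect sizes are specified as *standardized* path coefficients; raw
coefficients and residual standard deviations are derived so that every
continuous node has unit marginal variance (the scale on which the default
coefficients 0.8 / 0.9 / -0.7 give reliable pairwise signal at n ~ 60).
All randomness flows from one integer seed through numpy SeedSequence
spawning, so regeneration is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "ScenarioSpec",
    "TruthRecord",
    "SimulatedQuadruple",
    "PanelData",
    "SCENARIO_EDGES",
    "simulate_ri_genotypes",
    "simulate_quadruple",
    "simulate_panel",
]

# Node labels of a quadruple: S = SDP, M = miRNA, G = gene, P = phenotype.
SCENARIO_EDGES: dict[str, list[tuple[str, str]]] = {
    "full_mediation": [("S", "M"), ("M", "G"), ("G", "P")],
    "mediation_no_gene": [("S", "M"), ("M", "P")],
    "direct_only": [("S", "P")],
    "null": [],
    "reverse_gene_to_mirna": [("S", "G"), ("G", "M"), ("M", "P")],
}

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "full_mediation": {"S->M": 0.8, "M->G": 0.9, "G->P": -0.7},
    "mediation_no_gene": {"S->M": 0.8, "M->P": 0.7},
    "direct_only": {"S->P": 0.8},
    "null": {},
    "reverse_gene_to_mirna": {"S->G": 0.8, "G->M": 0.9, "M->P": 0.7},
}

_QUAD_NODES = ("S", "M", "G", "P")


@dataclass
class ScenarioSpec:
    """Generating parameters for one causal quadruple.

    ``effect_sizes`` maps edge labels (``"S->M"`` etc.) to standardized path
    coefficients; omitted edges of the scenario default to the module
    defaults. ``noise_sds`` may fix residual standard deviations per node;
    nodes left unset get the value implied by unit marginal variance.
    """

    scenario: str = "full_mediation"
    n_strains: int = 60
    effect_sizes: dict[str, float] = field(default_factory=dict)
    noise_sds: dict[str, float] = field(default_factory=dict)
    replicates_per_strain: int = 3
    replicate_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_EDGES:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"expected one of {sorted(SCENARIO_EDGES)}"
            )
        if self.n_strains < 4:
            raise ValueError("n_strains must be >= 4")
        if self.replicates_per_strain < 1:
            raise ValueError("need at least one replicate per strain")
        for node, sd in self.noise_sds.items():
            if not sd > 0:
                raise ValueError(f"noise sd for {node} must be > 0")
        for edge, b in self.effect_sizes.items():
            if not math.isfinite(b):
                raise ValueError(f"non-finite effect size for {edge}")

    def resolved_effects(self) -> dict[str, float]:
        eff = dict(DEFAULT_EFFECTS[self.scenario])
        eff.update(self.effect_sizes)
        return eff


@dataclass
class TruthRecord:
    """Ground-truth DAG and generating parameters of a simulated quadruple."""

    true_dag: list[tuple[str, str]]
    params: dict

    def __post_init__(self) -> None:
        import networkx as nx

        g = nx.DiGraph(self.true_dag)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("true DAG contains a cycle")
        labels = self.params.get("node_labels", {})
        s = labels.get("S", "S")
        p = labels.get("P", "P")
        if any(v == s for _, v in self.true_dag):
            raise ValueError("SDP node has a parent in the true DAG")
        if any(u == p for u, _ in self.true_dag):
            raise ValueError("phenotype node has a child in the true DAG")

    def to_json(self) -> str:
        return json.dumps(
            {"true_dag": [list(e) for e in self.true_dag], "params": self.params},
            indent=2,
            default=str,
        )


@dataclass
class SimulatedQuadruple:
    """Replicate-level tables plus truth for one simulated quadruple."""

    sdp: pd.Series
    mirna_replicates: pd.DataFrame
    gene_replicates: pd.DataFrame
    phenotype: pd.Series
    truth: TruthRecord
    strain_values: pd.DataFrame  # strain-level S, M, G, P (noise-free of replicate error)

    def strain_frame(self) -> pd.DataFrame:
        """Strain-level S/M/G/P frame with expression as replicate means."""
        m = self.mirna_replicates.groupby("strain")["M"].mean()
        g = self.gene_replicates.groupby("strain")["G"].mean()
        return pd.DataFrame(
            {"S": self.sdp, "M": m, "G": g, "P": self.phenotype}
        ).loc[self.sdp.index]


def _structural_params(
    edges: list[tuple[str, str]],
    effects: dict[str, float],
    noise_sds: dict[str, float],
) -> tuple[dict[str, dict[str, float]], dict[str, float]]:
    """Raw coefficients and residual sds giving unit marginal variances.

    Standardized coefficients are converted with b_raw = beta * sd(child) /
    sd(parent); parents within these scenarios are independent, so the
    residual variance of a unit-variance child is 1 - sum(beta^2). The SDP is
    Bernoulli(0.5), sd 0.5.
    """
    import networkx as nx

    marginal_sd = {"S": 0.5}
    coeffs: dict[str, dict[str, float]] = {}
    resid_sd: dict[str, float] = {}
    g = nx.DiGraph(edges)
    g.add_nodes_from(_QUAD_NODES)
    for node in nx.topological_sort(g):
        if node == "S":
            continue
        parents = sorted(g.predecessors(node))
        betas = {p: effects.get(f"{p}->{node}", 0.0) for p in parents}
        explained = sum(b * b for b in betas.values())
        if node in noise_sds:
            sd = noise_sds[node]
        else:
            if explained >= 1.0:
                raise ValueError(
                    f"standardized effects into {node} explain >= 100% variance"
                )
            sd = math.sqrt(1.0 - explained)
        coeffs[node] = {p: b / marginal_sd[p] for p, b in betas.items()}
        resid_sd[node] = sd
        marginal_sd[node] = math.sqrt(
            sum((coeffs[node][p] * marginal_sd[p]) ** 2 for p in parents) + sd * sd
        )
    return coeffs, resid_sd


def simulate_quadruple(spec: ScenarioSpec) -> SimulatedQuadruple:
    """Draw one SDP-miRNA-gene-phenotype quadruple under the scenario's truth.

    The SDP is Bernoulli(0.5) per strain; each continuous node is intercept
    (zero) plus coefficient x parent plus Gaussian noise, sampled in
    topological order of the true DAG. Expression nodes are emitted at
    replicate level with additional within-strain noise; the phenotype is
    generated from the strain-level (replicate-free) values.
    """
    import networkx as nx

    edges = SCENARIO_EDGES[spec.scenario]
    effects = spec.resolved_effects()
    coeffs, resid_sd = _structural_params(edges, effects, spec.noise_sds)

    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    strains = [f"strain{i + 1:03d}" for i in range(spec.n_strains)]

    g = nx.DiGraph(edges)
    g.add_nodes_from(_QUAD_NODES)
    values: dict[str, np.ndarray] = {}
    values["S"] = rng.binomial(1, 0.5, size=spec.n_strains).astype(float)
    for node in nx.topological_sort(g):
        if node == "S":
            continue
        mean = np.zeros(spec.n_strains)
        for p, b in coeffs[node].items():
            mean = mean + b * values[p]
        values[node] = mean + rng.normal(0.0, resid_sd[node], size=spec.n_strains)

    def replicate_table(node: str) -> pd.DataFrame:
        rows = []
        for i, strain in enumerate(strains):
            for r in range(spec.replicates_per_strain):
                noise = rng.normal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 0.0
                rows.append((strain, r + 1, values[node][i] + noise))
        return pd.DataFrame(rows, columns=["strain", "replicate", node])

    truth = TruthRecord(
        true_dag=list(edges),
        params={
            "scenario": spec.scenario,
            "n_strains": spec.n_strains,
            "standardized_effects": effects,
            "raw_coefficients": coeffs,
            "residual_sds": resid_sd,
            "replicates_per_strain": spec.replicates_per_strain,
            "replicate_sd": spec.replicate_sd,
            "seed": spec.seed,
            "node_labels": {k: k for k in _QUAD_NODES},
        },
    )
    return SimulatedQuadruple(
        sdp=pd.Series(values["S"], index=strains, name="S"),
        mirna_replicates=replicate_table("M"),
        gene_replicates=replicate_table("G"),
        phenotype=pd.Series(values["P"], index=strains, name="P"),
        truth=truth,
        strain_values=pd.DataFrame(values, index=strains)[list(_QUAD_NODES)],
    )


def simulate_ri_genotypes(
    n_strains: int,
    n_snps: int,
    chrom_lengths: dict | None = None,
    flip_prob: float = 0.005,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate RI-strain genotypes as two-parent mosaics.

    Per strain and chromosome, the parental origin of consecutive SNPs
    follows a two-state Markov chain with switch probability ``flip_prob``
    per inter-SNP interval and Bernoulli(0.5) initial state. SNP counts are
    apportioned to chromosomes proportionally to their lengths and positions
    drawn uniformly. Calls are emitted as allele letters (parent A -> "A",
    parent B -> "G") so the informative-SNP filter path is exercised.
    """
    if not 0.0 <= flip_prob <= 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5]")
    if chrom_lengths is None:
        chrom_lengths = {str(c): 100_000_000 for c in range(1, 5)}
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    counts = {c: max(1, int(round(n_snps * chrom_lengths[c] / total))) for c in chroms}
    # trim/pad to exactly n_snps, deterministically
    while sum(counts.values()) > n_snps:
        counts[max(chroms, key=lambda c: counts[c])] -= 1
    while sum(counts.values()) < n_snps:
        counts[min(chroms, key=lambda c: counts[c])] += 1

    snp_ids, chrom_col, pos_col = [], [], []
    origin = np.empty((n_strains, n_snps), dtype=np.int8)
    j = 0
    for c in chroms:
        k = counts[c]
        pos = np.sort(rng.integers(1, chrom_lengths[c] + 1, size=k))
        for p in pos:
            snp_ids.append(f"snp_{c}_{j + 1:05d}")
            chrom_col.append(c)
            pos_col.append(int(p))
            j += 1
        state = rng.binomial(1, 0.5, size=n_strains).astype(np.int8)
        block = np.empty((n_strains, k), dtype=np.int8)
        block[:, 0] = state
        for i in range(1, k):
            flips = rng.random(n_strains) < flip_prob
            state = np.where(flips, 1 - state, state).astype(np.int8)
            block[:, i] = state
        origin[:, j - k : j] = block

    strains = [f"strain{i + 1:03d}" for i in range(n_strains)]
    letters = np.where(origin == 0, "A", "G")
    calls = pd.DataFrame(letters, index=strains, columns=snp_ids)
    parental = pd.DataFrame(
        {"parent_l": "A", "parent_s": "G"}, index=pd.Index(snp_ids)
    )
    positions = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col}, index=pd.Index(snp_ids)
    )
    return GenotypeMatrix(calls=calls, parental_alleles=parental, positions=positions)


@dataclass
class PanelData:
    """A complete simulated input set for the pipeline, with ground truth."""

    genotypes: GenotypeMatrix
    mirna_replicates: pd.DataFrame   # strain, replicate, one column per miRNA
    gene_replicates: pd.DataFrame
    phenotypes: PhenotypeTable
    mirna_positions: pd.DataFrame
    gene_positions: pd.DataFrame
    truths: list[TruthRecord]

    def write(self, out_dir: str | Path) -> None:
        """Emit the plain-TSV input dialects plus the truth records as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        g = self.genotypes
        geno = pd.DataFrame(
            {
                "snp": g.snp_ids,
                "chrom": g.positions["chrom"].values,
                "pos": g.positions["pos"].values,
            }
        )
        for strain in g.strain_ids:
            geno[strain] = g.calls.loc[strain].values
        geno["parentA"] = g.parental_alleles["parent_l"].values
        geno["parentB"] = g.parental_alleles["parent_s"].values
        geno.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        (out / "genotypes.json").write_text(
            json.dumps({"parents": ["parentA", "parentB"]}) + "\n"
        )
        self.mirna_replicates.to_csv(out / "mirna_replicates.tsv", sep="\t", index=False)
        self.gene_replicates.to_csv(out / "gene_replicates.tsv", sep="\t", index=False)
        self.phenotypes.values.rename_axis("strain").to_csv(
            out / "phenotypes.tsv", sep="\t"
        )
        self.mirna_positions.rename_axis("feature").to_csv(
            out / "mirna_positions.tsv", sep="\t"
        )
        self.gene_positions.rename_axis("feature").to_csv(
            out / "gene_positions.tsv", sep="\t"
        )
        (out / "truth.json").write_text(
            json.dumps(
                [json.loads(t.to_json()) for t in self.truths], indent=2
            )
            + "\n"
        )


def simulate_panel(
    n_strains: int = 60,
    n_mirna: int = 30,
    n_genes: int = 30,
    n_phenotypes: int = 1,
    n_embedded_quadruples: int = 1,
    seed: int = 0,
    n_snps: int = 200,
    flip_prob: float = 0.005,
    scenario: str = "full_mediation",
    effect_sizes: dict[str, float] | None = None,
    replicates_per_strain: int = 3,
    replicate_sd: float = 0.3,
    out_dir: str | Path | None = None,
) -> PanelData:
    """Simulate a full pipeline input set with embedded causal quadruples.

    Background miRNAs, genes and phenotypes are independent standard
    Gaussians (plus replicate noise for expression). Each embedded quadruple
    is wired per ``scenario`` onto a randomly chosen SDP locus whose minor
    allele is carried by at least a quarter of the strains (so the anchor is
    informative), replacing one miRNA, one gene and driving one phenotype.
    """
    if n_embedded_quadruples > min(n_mirna, n_genes):
        raise ValueError("more embedded quadruples than available features")
    if n_embedded_quadruples > n_phenotypes:
        raise ValueError("more embedded quadruples than phenotypes")
    ss = np.random.SeedSequence(seed)
    geno_ss, pick_ss, quad_ss, bg_ss = ss.spawn(4)
    rng = np.random.default_rng(pick_ss)

    genotypes = simulate_ri_genotypes(
        n_strains, n_snps, flip_prob=flip_prob,
        seed=int(np.random.default_rng(geno_ss).integers(2**31)),
    )
    from .data_io import collapse_to_sdps, filter_informative_snps

    sdps = collapse_to_sdps(filter_informative_snps(genotypes))
    freqs = sdps.patterns.mean(axis=1)
    balanced = [
        s for s in sdps.sdp_ids if 0.25 <= freqs[s] <= 0.75
    ]
    if len(balanced) < n_embedded_quadruples:
        balanced = list(sdps.sdp_ids)
    anchors = [str(a) for a in rng.choice(balanced, size=n_embedded_quadruples, replace=False)]

    strains = sdps.strain_ids
    mirna_ids = [f"mir{i + 1:03d}" for i in range(n_mirna)]
    gene_ids = [f"gene{i + 1:03d}" for i in range(n_genes)]
    pheno_ids = [f"pheno{i + 1}" for i in range(n_phenotypes)]

    emb_mirna = [str(a) for a in rng.choice(mirna_ids, size=n_embedded_quadruples, replace=False)]
    emb_gene = [str(a) for a in rng.choice(gene_ids, size=n_embedded_quadruples, replace=False)]
    emb_pheno = [str(a) for a in rng.choice(pheno_ids, size=n_embedded_quadruples, replace=False)]

    bg_rng = np.random.default_rng(bg_ss)
    strain_mirna = pd.DataFrame(
        bg_rng.normal(size=(len(strains), n_mirna)), index=strains, columns=mirna_ids
    )
    strain_gene = pd.DataFrame(
        bg_rng.normal(size=(len(strains), n_genes)), index=strains, columns=gene_ids
    )
    pheno_vals = pd.DataFrame(
        bg_rng.normal(size=(len(strains), n_phenotypes)),
        index=strains,
        columns=pheno_ids,
    )

    truths: list[TruthRecord] = []
    quad_children = quad_ss.spawn(max(1, n_embedded_quadruples))
    for q in range(n_embedded_quadruples):
        spec = ScenarioSpec(
            scenario=scenario,
            n_strains=len(strains),
            effect_sizes=effect_sizes or {},
            replicates_per_strain=replicates_per_strain,
            replicate_sd=replicate_sd,
            seed=int(np.random.default_rng(quad_children[q]).integers(2**31)),
        )
        edges = SCENARIO_EDGES[scenario]
        effects = spec.resolved_effects()
        coeffs, resid_sd = _structural_params(edges, effects, spec.noise_sds)
        qrng = np.random.default_rng(spec.seed)
        import networkx as nx

        g = nx.DiGraph(edges)
        g.add_nodes_from(_QUAD_NODES)
        values = {"S": sdps.patterns.loc[anchors[q]].to_numpy(dtype=float)}
        for node in nx.topological_sort(g):
            if node == "S":
                continue
            mean = np.zeros(len(strains))
            for p, b in coeffs[node].items():
                mean = mean + b * values[p]
            values[node] = mean + qrng.normal(0.0, resid_sd[node], size=len(strains))
        strain_mirna[emb_mirna[q]] = values["M"]
        strain_gene[emb_gene[q]] = values["G"]
        pheno_vals[emb_pheno[q]] = values["P"]
        labels = {
            "S": anchors[q],
            "M": emb_mirna[q],
            "G": emb_gene[q],
            "P": emb_pheno[q],
        }
        truths.append(
            TruthRecord(
                true_dag=[(labels[u], labels[v]) for u, v in edges],
                params={
                    "scenario": scenario,
                    "standardized_effects": effects,
                    "raw_coefficients": coeffs,
                    "residual_sds": resid_sd,
                    "node_labels": labels,
                    "seed": spec.seed,
                },
            )
        )

    def replicate_long(strain_level: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for strain in strains:
            for r in range(replicates_per_strain):
                noise = bg_rng.normal(0.0, replicate_sd, size=strain_level.shape[1])
                rows.append(
                    [strain, r + 1, *(strain_level.loc[strain].to_numpy() + noise)]
                )
        return pd.DataFrame(
            rows, columns=["strain", "replicate", *strain_level.columns]
        )

    chroms = list(dict.fromkeys(genotypes.positions["chrom"]))
    def random_positions(ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": bg_rng.choice(chroms, size=len(ids)),
                "start": bg_rng.integers(1, 100_000_000, size=len(ids)),
            },
            index=pd.Index(ids),
        )

    panel = PanelData(
        genotypes=genotypes,
        mirna_replicates=replicate_long(strain_mirna),
        gene_replicates=replicate_long(strain_gene),
        phenotypes=PhenotypeTable(values=pheno_vals),
        mirna_positions=random_positions(mirna_ids),
        gene_positions=random_positions(gene_ids),
        truths=truths,
    )
    if out_dir is not None:
        panel.write(out_dir)
    return panel
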