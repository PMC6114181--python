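"""End-to-end orchestration: screen, mediate, expand, predict, per phenotype."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, expansion, mediation
from .bn_core import NetworkStructure, NodeRole
from .data_io import (
    AlignedDataset,
    ExpressionMatrix,
    PhenotypeTable,
    SDPTable,
    align_for_phenotype,
    collapse_to_sdps,
    filter_informative_snps,
    read_expression_tsv,
    read_genotype_tsv,
    read_phenotype_tsv,
)
from .expansion import AveragedNetwork, LocusGroup
from .mediation import MediationDecision
from .prediction import (
    InterventionResult,
    fit_network_parameters,
    predict_phenotype_change,
)

logger = logging.getLogger("mirmediation")

__all__ = ["PipelineConfig", "PhenotypeResult", "run_pipeline", "load_inputs"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the standard defaults."""

    triplet_p: float = association.TRIPLET_P_DEFAULT
    quadruple_p: float = association.QUADRUPLE_P_DEFAULT
    bic_delta_mediation: float = mediation.BIC_DELTA_MEDIATION_DEFAULT
    bic_delta_gene: float = mediation.BIC_DELTA_GENE_DEFAULT
    locus_window_bp: int = expansion.LOCUS_WINDOW_BP_DEFAULT
    n_boot: int = expansion.N_BOOT_DEFAULT
    retention: float = expansion.RETENTION_DEFAULT
    direction_denominator: str = "edge_present"
    exhaustive_if_small: int = expansion.EXHAUSTIVE_IF_SMALL_DEFAULT
    seed: int = 0


@dataclass
class PhenotypeResult:
    phenotype_id: str
    dataset: AlignedDataset
    quadruples: list = field(default_factory=list)
    decisions: list[MediationDecision] = field(default_factory=list)
    groups: list[LocusGroup] = field(default_factory=list)
    networks: list[tuple[LocusGroup, AveragedNetwork]] = field(default_factory=list)
    predictions: list[InterventionResult] = field(default_factory=list)


def run_pipeline(
    sdps: SDPTable,
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    config: PipelineConfig | None = None,
    phenotype_ids: list[str] | None = None,
) -> dict[str, PhenotypeResult]:
    """Run the full analysis for each phenotype on its aligned strain set."""
    cfg = config or PipelineConfig()
    results: dict[str, PhenotypeResult] = {}
    for pid in phenotype_ids or phenotypes.phenotype_ids:
        dataset = align_for_phenotype(sdps, mirna, genes, phenotypes, pid)
        res = PhenotypeResult(phenotype_id=pid, dataset=dataset)
        triplets = association.find_cohesive_triplets(dataset, cfg.triplet_p)
        res.quadruples = association.extend_to_quadruples(
            triplets, dataset, cfg.quadruple_p
        )
        logger.info(
            "%s: %d cohesive triplets, %d quadruples",
            pid, len(triplets), len(res.quadruples),
        )
        res.decisions = mediation.run_mediation_screen(
            res.quadruples, dataset,
            threshold_step1=cfg.bic_delta_mediation,
            threshold_step2=cfg.bic_delta_gene,
        )
        res.groups = expansion.group_by_locus(
            res.decisions, sdps, window_bp=cfg.locus_window_bp
        )
        for gi, group in enumerate(res.groups):
            data, roles = expansion.group_dataset(group, dataset)
            avg = expansion.bootstrap_average(
                data, roles,
                n_boot=cfg.n_boot,
                retention=cfg.retention,
                seed=cfg.seed + gi,
                direction_denominator=cfg.direction_denominator,
                exhaustive_if_small=cfg.exhaustive_if_small,
            )
            res.networks.append((group, avg))
            res.predictions.extend(_predict_for_network(avg, data, roles))
        results[pid] = res
    return results


def _predict_for_network(
    avg: AveragedNetwork, data: pd.DataFrame, roles: list[NodeRole]
) -> list[InterventionResult]:
    if not avg.retained_edges:
        return []
    keep = [r for r in roles if r.label not in avg.dropped_nodes]
    if not any(r.kind == "continuous_phenotype" for r in keep):
        return []
    structure = NetworkStructure(tuple(keep), frozenset(avg.retained_edges))
    fitted = fit_network_parameters(structure, data[[r.label for r in keep]])
    out = []
    for r in keep:
        if r.kind != "continuous_intermediate":
            continue
        for span in ("two_quartile", "four_quartile"):
            out.append(predict_phenotype_change(fitted, r.label, span))
    return out


def load_inputs(in_dir: str | Path) -> tuple[SDPTable, ExpressionMatrix,
                                             ExpressionMatrix, PhenotypeTable]:
    """Load the TSV input set written by the simulator (or hand-prepared)."""
    d = Path(in_dir)
    genotypes = read_genotype_tsv(d / "genotypes.tsv", d / "genotypes.json")
    sdps = collapse_to_sdps(filter_informative_snps(genotypes))
    mirna = read_expression_tsv(
        d / "mirna_replicates.tsv",
        d / "mirna_positions.tsv" if (d / "mirna_positions.tsv").exists() else None,
    )
    genes = read_expression_tsv(
        d / "gene_replicates.tsv",
        d / "gene_positions.tsv" if (d / "gene_positions.tsv").exists() else None,
    )
    phenotypes = read_phenotype_tsv(d / "phenotypes.tsv")
    return sdps, mirna, genes, phenotypes
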