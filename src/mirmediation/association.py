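"""Cohesive-triplet and -quadruple screening by pairwise Pearson correlation.

A triplet (SDP, miRNA, gene) is *cohesive* when all three pairwise Pearson
correlations are nominally significant (default p < 1e-3, two-sided); a
cohesive quadruple adds a phenotype significantly associated (default
p < 0.05) with each of the three components. Correlations with the binary
SDP are point-biserial, which is the Pearson correlation computed on the
0/1 coding. No multiple-testing correction is applied at this stage; the
thresholds are nominal by design and stringency comes from the downstream
Bayesian-network filters.

The triplet search is staged — SDP-miRNA pairs first, then SDP-gene, then
miRNA-gene within survivors — which is provably identical to the brute-force
triple loop because the cohesion predicate is a conjunction of pairwise
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AlignedDataset

__all__ = [
    "CohesiveTriplet",
    "CohesiveQuadruple",
    "pearson_with_pvalue",
    "find_cohesive_triplets",
    "extend_to_quadruples",
    "quadruples_to_frame",
]

TRIPLET_P_DEFAULT = 1e-3
QUADRUPLE_P_DEFAULT = 0.05


@dataclass(frozen=True)
class CohesiveTriplet:
    sdp_id: str
    mirna_id: str
    gene_id: str
    r_sm: float
    r_sg: float
    r_mg: float
    p_sm: float
    p_sg: float
    p_mg: float
    n_used: int


@dataclass(frozen=True)
class CohesiveQuadruple:
    triplet: CohesiveTriplet
    phenotype_id: str
    r_sp: float
    r_mp: float
    r_gp: float
    p_sp: float
    p_mp: float
    p_gp: float
    n_used: int


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value on n-2 df.

    ``x`` may be a 0/1 marker vector (point-biserial case). |r| = 1 gives
    p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input (degenerate marker or flat values)")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0 - 1e-12:  # exactly collinear up to rounding
        return (1.0 if r > 0 else -1.0), 0.0
    return r, float(res.pvalue)


def _corr_pvalues(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Column-by-column Pearson r and p matrices between two aligned frames."""
    n = len(a)
    az = _standardize(a.to_numpy(dtype=float))
    bz = _standardize(b.to_numpy(dtype=float))
    r = az.T @ bz / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def _standardize(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance column in correlation screen")
    return (m - mu) / sd


def find_cohesive_triplets(
    dataset: AlignedDataset, p_threshold: float = TRIPLET_P_DEFAULT
) -> list[CohesiveTriplet]:
    """Exhaustively screen SDP x miRNA x gene triplets, via staged pruning.

    SDPs that are constant on the aligned strains are skipped (a degenerate
    marker carries no association signal). Output order is (sdp, mirna, gene)
    lexicographic over the input feature orders.
    """
    sdp_ids = dataset.sdps.sdp_ids
    mirna, genes = dataset.mirna, dataset.genes
    if not sdp_ids or mirna.shape[1] == 0 or genes.shape[1] == 0:
        return []
    n = dataset.n
    sdp_mat = dataset.sdps.patterns.T.astype(float)  # strains x sdps
    nondegenerate = [s for s in sdp_ids if sdp_mat[s].nunique() > 1]
    if not nondegenerate:
        return []
    sdp_mat = sdp_mat[nondegenerate]

    r_sm, p_sm = _corr_pvalues(sdp_mat, mirna)
    r_sg, p_sg = _corr_pvalues(sdp_mat, genes)
    r_mg, p_mg = _corr_pvalues(mirna, genes)

    mirna_ids = list(mirna.columns)
    gene_ids = list(genes.columns)
    triplets: list[CohesiveTriplet] = []
    for i, sdp in enumerate(nondegenerate):
        m_hits = np.flatnonzero(p_sm[i] < p_threshold)
        if m_hits.size == 0:
            continue
        g_hits = np.flatnonzero(p_sg[i] < p_threshold)
        if g_hits.size == 0:
            continue
        for mi in m_hits:
            for gi in g_hits:
                if p_mg[mi, gi] < p_threshold:
                    triplets.append(
                        CohesiveTriplet(
                            sdp_id=sdp,
                            mirna_id=mirna_ids[mi],
                            gene_id=gene_ids[gi],
                            r_sm=float(r_sm[i, mi]),
                            r_sg=float(r_sg[i, gi]),
                            r_mg=float(r_mg[mi, gi]),
                            p_sm=float(p_sm[i, mi]),
                            p_sg=float(p_sg[i, gi]),
                            p_mg=float(p_mg[mi, gi]),
                            n_used=n,
                        )
                    )
    return triplets


def extend_to_quadruples(
    triplets: list[CohesiveTriplet],
    dataset: AlignedDataset,
    p_threshold: float = QUADRUPLE_P_DEFAULT,
) -> list[CohesiveQuadruple]:
    """Keep triplets whose phenotype correlates with all three components."""
    if not triplets:
        return []
    pheno = dataset.phenotype.to_numpy(dtype=float)
    pid = str(dataset.phenotype.name)
    cache: dict[tuple[str, str], tuple[float, float]] = {}

    def corr(kind: str, feat: str) -> tuple[float, float]:
        key = (kind, feat)
        if key not in cache:
            if kind == "sdp":
                x = dataset.sdp_vector(feat)
            elif kind == "mirna":
                x = dataset.mirna[feat].to_numpy(dtype=float)
            else:
                x = dataset.genes[feat].to_numpy(dtype=float)
            cache[key] = pearson_with_pvalue(x, pheno)
        return cache[key]

    out: list[CohesiveQuadruple] = []
    for t in triplets:
        r_sp, p_sp = corr("sdp", t.sdp_id)
        if p_sp >= p_threshold:
            continue
        r_mp, p_mp = corr("mirna", t.mirna_id)
        if p_mp >= p_threshold:
            continue
        r_gp, p_gp = corr("gene", t.gene_id)
        if p_gp >= p_threshold:
            continue
        out.append(
            CohesiveQuadruple(
                triplet=t,
                phenotype_id=pid,
                r_sp=r_sp, r_mp=r_mp, r_gp=r_gp,
                p_sp=p_sp, p_mp=p_mp, p_gp=p_gp,
                n_used=dataset.n,
            )
        )
    return out


def quadruples_to_frame(quadruples: list[CohesiveQuadruple]) -> pd.DataFrame:
    """Flatten quadruples to the TSV-ready result table."""
    rows = []
    for q in quadruples:
        t = q.triplet
        rows.append(
            {
                "sdp": t.sdp_id, "mirna": t.mirna_id, "gene": t.gene_id,
                "phenotype": q.phenotype_id,
                "r_sm": t.r_sm, "p_sm": t.p_sm,
                "r_sg": t.r_sg, "p_sg": t.p_sg,
                "r_mg": t.r_mg, "p_mg": t.p_mg,
                "r_sp": q.r_sp, "p_sp": q.p_sp,
                "r_mp": q.r_mp, "p_mp": q.p_mp,
                "r_gp": q.r_gp, "p_gp": q.p_gp,
                "n": q.n_used,
            }
        )
    return pd.DataFrame(rows)
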