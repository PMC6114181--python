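"""Input containers and harmonization for RI-panel genotype/expression/phenotype data.

The pipeline consumes already-normalized tables: binary genotypes coded by
parental origin, variance-stabilized miRNA expression, log2 gene expression,
and quantitative phenotypes, all indexed by strain. This module reads the
plain TSV dialects, collapses SNPs in complete linkage disequilibrium to
strain distribution patterns (SDPs), averages expression replicates within a
strain, and intersects strain sets per phenotype so that every downstream
statistic is computed on one consistent strain ordering.

Coordinates are 1-based inclusive base pairs throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mirmediation")

__all__ = [
    "GenotypeMatrix",
    "SDPTable",
    "ExpressionMatrix",
    "PhenotypeTable",
    "AlignedDataset",
    "filter_informative_snps",
    "collapse_to_sdps",
    "collapse_replicates",
    "align_for_phenotype",
    "read_genotype_tsv",
    "read_expression_tsv",
    "read_phenotype_tsv",
    "read_positions_tsv",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Strain-level SNP calls with parental reference alleles.

    Parameters
    ----------
    calls
        strains x SNPs frame. Before informative filtering the entries are
        allele codes (strings, NaN = missing); after filtering they are
        0/1 integers coded by parental origin (0 = allele of the first
        parental strain, 1 = allele of the second).
    parental_alleles
        SNPs x ``[parent_l, parent_s]`` frame with the two parental alleles.
    positions
        SNPs x ``[chrom, pos]`` frame (1-based bp).
    recoded
        True once calls are 0/1 parental-origin codes.
    """

    calls: pd.DataFrame
    parental_alleles: pd.DataFrame
    positions: pd.DataFrame
    recoded: bool = False

    def __post_init__(self) -> None:
        snps = list(self.calls.columns)
        if list(self.parental_alleles.index) != snps:
            self.parental_alleles = self.parental_alleles.loc[snps]
        missing_pos = set(snps) - set(self.positions.index)
        if missing_pos:
            raise ValueError(f"SNPs without positions: {sorted(missing_pos)[:5]} ...")
        self.positions = self.positions.loc[snps]

    @property
    def strain_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class SDPTable:
    """Unique strain distribution patterns with member SNPs and genomic spans.

    A strain distribution pattern (SDP) is the vector of parental-origin
    alleles across the panel; SNPs sharing a pattern are in complete linkage
    disequilibrium (no recombination between them in any strain) and act as a
    single genetic marker.

    ``patterns`` is an SDPs x strains 0/1 frame with pairwise-distinct rows.
    ``spans`` maps each SDP to per-chromosome (chrom, min bp, max bp) tuples
    covering its member SNPs; ``chrom`` assigns the SDP to the chromosome
    holding the majority of its members (for locus-window grouping).
    """

    patterns: pd.DataFrame
    members: dict[str, list[str]]
    spans: dict[str, list[tuple]] = field(default_factory=dict)
    chrom: dict[str, object] = field(default_factory=dict)
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            arr = self.patterns.to_numpy()
            if len(np.unique(arr, axis=0)) != arr.shape[0]:
                raise ValueError("SDP patterns are not pairwise distinct")

    @property
    def sdp_ids(self) -> list[str]:
        return list(self.patterns.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.patterns.columns)

    def midpoint(self, sdp_id: str) -> tuple:
        """(chrom, bp midpoint) of the SDP's span on its assigned chromosome."""
        chrom = self.chrom[sdp_id]
        for c, lo, hi in self.spans[sdp_id]:
            if c == chrom:
                return chrom, (lo + hi) / 2.0
        raise KeyError(sdp_id)

    def restrict(self, strains: list[str]) -> "SDPTable":
        """Restrict patterns to a strain subset (distinctness not re-enforced)."""
        return SDPTable(
            patterns=self.patterns.loc[:, list(strains)],
            members=self.members,
            spans=self.spans,
            chrom=self.chrom,
            validate=False,
        )


@dataclass
class ExpressionMatrix:
    """Strain x feature continuous expression (one row per strain)."""

    values: pd.DataFrame
    feature_positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PhenotypeTable:
    """Strain x phenotype quantitative values; NaN marks strains absent from a study."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        n_obs = self.values.notna().sum(axis=0)
        bad = n_obs[n_obs < 3]
        if len(bad):
            raise ValueError(
                f"phenotypes with fewer than 3 observed strains: {list(bad.index)}"
            )

    @property
    def phenotype_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AlignedDataset:
    """Strain-intersected bundle for one phenotype's analysis.

    All components are indexed by the identical ordered strain list; ``n`` is
    the sample size entering every likelihood and correlation computed
    downstream.
    """

    strain_ids: list[str]
    sdps: SDPTable
    mirna: pd.DataFrame
    genes: pd.DataFrame
    phenotype: pd.Series
    n: int

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"aligned dataset has n={self.n} < 4 strains")
        for name, idx in (
            ("sdps", self.sdps.strain_ids),
            ("mirna", list(self.mirna.index)),
            ("genes", list(self.genes.index)),
            ("phenotype", list(self.phenotype.index)),
        ):
            if list(idx) != self.strain_ids:
                raise ValueError(f"{name} not aligned to the dataset strain order")
        if self.phenotype.isna().any():
            raise ValueError("aligned phenotype contains missing values")

    def sdp_vector(self, sdp_id: str) -> np.ndarray:
        return self.sdps.patterns.loc[sdp_id].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_informative_snps(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Keep SNPs with differing parental alleles and complete calls; recode 0/1.

    A SNP is informative when its two parental alleles differ and every strain
    has a non-missing call matching one of the two parental alleles. Retained
    calls are recoded by parental origin (0 = first parent's allele, 1 =
    second parent's). SNP order is preserved.
    """
    if genotypes.recoded:
        return genotypes
    pa = genotypes.parental_alleles
    calls = genotypes.calls
    keep: list[str] = []
    coded = {}
    for snp in genotypes.snp_ids:
        al, as_ = pa.loc[snp, "parent_l"], pa.loc[snp, "parent_s"]
        if pd.isna(al) or pd.isna(as_):
            raise ValueError(f"SNP {snp} lacks parental alleles")
        if al == as_:
            continue
        col = calls[snp]
        if col.isna().any():
            continue
        is_l = col == al
        is_s = col == as_
        if not (is_l | is_s).all():
            continue  # a call outside the parental allele set counts as missing
        keep.append(snp)
        coded[snp] = is_s.astype(np.int8)
    if not keep:
        raise ValueError("no informative SNPs remain after filtering")
    return GenotypeMatrix(
        calls=pd.DataFrame(coded, index=genotypes.calls.index)[keep],
        parental_alleles=pa.loc[keep],
        positions=genotypes.positions.loc[keep],
        recoded=True,
    )


def collapse_to_sdps(genotypes: GenotypeMatrix) -> SDPTable:
    """Group SNPs with bit-identical strain vectors into strain distribution patterns.

    Two SNPs share an SDP iff their 0/1 parental-origin vectors are exactly
    equal across the panel (complete LD). Complementary vectors are *not*
    merged: in a two-parent RI panel a complemented pattern would imply a
    recombination between the two SNPs in every strain. SDPs are numbered in
    order of first occurrence along the input SNP order.
    """
    if not genotypes.recoded:
        genotypes = filter_informative_snps(genotypes)
    calls = genotypes.calls
    pattern_to_sdp: dict[bytes, str] = {}
    members: dict[str, list[str]] = {}
    rows: list[np.ndarray] = []
    for snp in genotypes.snp_ids:
        vec = calls[snp].to_numpy(dtype=np.int8)
        key = vec.tobytes()
        if key not in pattern_to_sdp:
            sdp_id = f"SDP{len(pattern_to_sdp) + 1:04d}"
            pattern_to_sdp[key] = sdp_id
            members[sdp_id] = []
            rows.append(vec)
        members[pattern_to_sdp[key]].append(snp)

    sdp_ids = list(members)
    patterns = pd.DataFrame(np.vstack(rows), index=sdp_ids, columns=calls.index)

    spans: dict[str, list[tuple]] = {}
    chrom_of: dict[str, object] = {}
    pos = genotypes.positions
    for sdp_id in sdp_ids:
        sub = pos.loc[members[sdp_id]]
        per_chrom = [
            (c, int(grp["pos"].min()), int(grp["pos"].max()))
            for c, grp in sub.groupby("chrom", sort=True)
        ]
        spans[sdp_id] = per_chrom
        if len(per_chrom) > 1:
            logger.warning(
                "SDP %s spans %d chromosomes; assigned to majority chromosome",
                sdp_id, len(per_chrom),
            )
        counts = sub["chrom"].value_counts()
        top = counts[counts == counts.max()].index
        chrom_of[sdp_id] = sorted(top, key=str)[0]
    return SDPTable(patterns=patterns, members=members, spans=spans, chrom=chrom_of)


def collapse_replicates(replicate_expression: pd.DataFrame) -> ExpressionMatrix:
    """Average biological replicates within a strain.

    ``replicate_expression`` is a long-ish table with columns ``strain``,
    ``replicate``, then one column per feature. The result has one row per
    strain holding the arithmetic mean over that strain's replicates.
    """
    df = replicate_expression
    if "strain" not in df.columns:
        raise ValueError("replicate table must have a 'strain' column")
    feat_cols = [c for c in df.columns if c not in ("strain", "replicate")]
    if not feat_cols:
        raise ValueError("replicate table has no feature columns")
    if df[feat_cols].isna().any().any():
        raise ValueError("missing replicate values are not supported")
    means = df.groupby("strain", sort=True)[feat_cols].mean()
    means.index.name = None
    return ExpressionMatrix(values=means)


def align_for_phenotype(
    sdps: SDPTable,
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    phenotype_id: str,
) -> AlignedDataset:
    """Intersect strain sets across all sources and one phenotype's observed strains.

    The strain set is the intersection of the genotype, miRNA, gene and
    phenotype sources, keeping only strains with a non-missing value for
    ``phenotype_id``; the output order is sorted so alignment does not depend
    on input ordering. Missing phenotypes are handled solely by exclusion.
    """
    if phenotype_id not in phenotypes.values.columns:
        raise KeyError(f"unknown phenotype {phenotype_id!r}")
    pheno = phenotypes.values[phenotype_id].dropna()
    common = (
        set(sdps.strain_ids)
        & set(mirna.strain_ids)
        & set(genes.strain_ids)
        & set(pheno.index)
    )
    strains = sorted(common)
    if len(strains) < 4:
        raise ValueError(
            f"only {len(strains)} strains shared across sources for {phenotype_id!r}"
        )
    return AlignedDataset(
        strain_ids=strains,
        sdps=sdps.restrict(strains),
        mirna=mirna.values.loc[strains],
        genes=genes.values.loc[strains],
        phenotype=pheno.loc[strains],
        n=len(strains),
    )


# ---------------------------------------------------------------------------
# File readers (plain TSV dialects + JSON/YAML sidecar)
# ---------------------------------------------------------------------------

def _read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_genotype_tsv(path: str | Path, sidecar: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV (rows = SNPs: id, chrom, pos, then strain calls).

    The sidecar (JSON or YAML) declares the two parental strain labels under
    ``parents``; their columns provide the per-SNP parental alleles and are
    removed from the panel call matrix.
    """
    meta = _read_sidecar(sidecar)
    parents = meta["parents"]
    if len(parents) != 2:
        raise ValueError("sidecar must declare exactly two parental strains")
    df = pd.read_csv(path, sep="\t", dtype=str)
    snp_col, chrom_col, pos_col = df.columns[:3]
    df = df.set_index(snp_col)
    positions = pd.DataFrame(
        {"chrom": df[chrom_col], "pos": df[pos_col].astype(int)}
    )
    strain_cols = [c for c in df.columns if c not in (chrom_col, pos_col)]
    for p in parents:
        if p not in strain_cols:
            raise ValueError(f"parental strain {p!r} missing from genotype columns")
    parental = pd.DataFrame(
        {"parent_l": df[parents[0]], "parent_s": df[parents[1]]}
    )
    panel = [c for c in strain_cols if c not in parents]
    calls = df[panel].T  # strains x SNPs
    calls = calls.where(calls.notna() & (calls != ""), np.nan)
    return GenotypeMatrix(calls=calls, parental_alleles=parental, positions=positions)


def read_expression_tsv(
    path: str | Path, positions: str | Path | None = None
) -> ExpressionMatrix:
    """Read expression as replicate-level (auto-collapsed) or strain x feature matrix."""
    df = pd.read_csv(path, sep="\t")
    if "replicate" in df.columns:
        mat = collapse_replicates(df)
    else:
        first = df.columns[0]
        mat = ExpressionMatrix(values=df.set_index(first).astype(float))
        mat.values.index.name = None
    if positions is not None:
        mat.feature_positions = read_positions_tsv(positions)
    return mat


def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    """Read a strain x phenotype matrix; empty cells are missing."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0]).astype(float)
    df.index.name = None
    return PhenotypeTable(values=df)


def read_positions_tsv(path: str | Path) -> pd.DataFrame:
    """Read feature positions (feature id, chromosome, start bp)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.columns = ["chrom", "start"][: len(df.columns)]
    df["start"] = df["start"].astype(int)
    return df
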