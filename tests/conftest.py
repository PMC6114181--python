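import numpy as np
import pandas as pd
import pytest

from mirmediation.bn_core import NodeRole
from mirmediation.data_io import GenotypeMatrix


QUAD_ROLES = [
    NodeRole("S", "sdp_binary_root"),
    NodeRole("M", "continuous_intermediate"),
    NodeRole("G", "continuous_intermediate"),
    NodeRole("P", "continuous_phenotype"),
]


@pytest.fixture
def quad_roles():
    return list(QUAD_ROLES)


@pytest.fixture
def toy_genotypes():
    """5 SNPs x 4 strains with the patterns [0011, 0011, 0101, 0101, 0011]."""
    strains = ["s1", "s2", "s3", "s4"]
    vectors = {
        "snp1": [0, 0, 1, 1],
        "snp2": [0, 0, 1, 1],
        "snp3": [0, 1, 0, 1],
        "snp4": [0, 1, 0, 1],
        "snp5": [0, 0, 1, 1],
    }
    calls = pd.DataFrame(
        {s: np.where(np.array(v), "G", "A") for s, v in vectors.items()},
        index=strains,
    )
    snps = list(vectors)
    parental = pd.DataFrame({"parent_l": "A", "parent_s": "G"}, index=pd.Index(snps))
    positions = pd.DataFrame(
        {"chrom": ["1"] * 5, "pos": [100, 200, 300, 400, 500]}, index=pd.Index(snps)
    )
    return GenotypeMatrix(calls=calls, parental_alleles=parental, positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
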