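import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pleiogene.synthetic_data import LDReference, default_gene_annotation, simulate_ld_reference

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_panel(rows):
    """LDReference with identity LD built from (snp_id, chrom, pos, a1, a2, maf) rows."""
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2", "maf"])
    df["block"] = 0
    return LDReference(blocks=[np.eye(len(df))], snp_index=df)


def make_sumstats(records):
    """Summary-statistic frame from (snp_id, chrom, pos, a1, a2, maf, beta, se) rows."""
    from scipy import stats

    df = pd.DataFrame(
        records, columns=["snp_id", "chrom", "pos", "a1", "a2", "maf", "beta", "se"]
    )
    df["z"] = df["beta"] / df["se"]
    df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    df["n"] = 10_000.0
    return df


@pytest.fixture(scope="session")
def ld_hetero():
    """Medium LD reference with heterogeneous AR(1) decay: 100 blocks of 50 SNPs."""
    return simulate_ld_reference(n_blocks=100, block_size=50, rho_ar1=(0.1, 0.9), seed=31)


@pytest.fixture(scope="session")
def annot5(ld_hetero):
    """1000 genes of 5 SNPs tiling the medium reference."""
    return default_gene_annotation(ld_hetero, snps_per_gene=5)
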