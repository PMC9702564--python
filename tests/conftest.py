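import numpy as np
import pytest

from reprocausal.harmonize import HarmonizedData
from reprocausal.sumstats_io import SummaryStatsTable, VariantRecord


@pytest.fixture
def worked3() -> HarmonizedData:
    """Three-SNP harmonized dataset used for hand-computed estimator values.

    gamma = (0.1, 0.2, 0.1), Gamma = (0.02, 0.05, 0.03),
    sigma_Y = (0.01, 0.01, 0.02): IVW weights (100, 400, 25),
    ratios (0.2, 0.25, 0.3).
    """
    return HarmonizedData.from_arrays(
        gamma=[0.1, 0.2, 0.1],
        sigma_x=[0.01, 0.01, 0.01],
        Gamma=[0.02, 0.05, 0.03],
        sigma_y=[0.01, 0.01, 0.02],
        variant_ids=["s1", "s2", "s3"],
    )


def make_variant(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-9,
    n=10000,
    chrom=None,
    pos=None,
) -> VariantRecord:
    return VariantRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        chrom=chrom,
        pos=pos,
    )


def make_table(records, name="trait", trait_type="exposure") -> SummaryStatsTable:
    return SummaryStatsTable.from_records(records, name, trait_type)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
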