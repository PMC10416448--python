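import numpy as np
import pytest
from hypothesis import settings

from mrkit.summary_io import GwasRecord, HarmonizedVariant

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(
    rsid="rs1",
    chrom=1,
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-6,
    n=18000,
) -> GwasRecord:
    return GwasRecord(
        rsid, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n
    )


def make_variant(
    rsid="rs1",
    beta_exp=0.1,
    se_exp=0.01,
    beta_out=0.05,
    se_out=0.02,
    eaf_exp=0.3,
    eaf_out=0.3,
    palindromic=False,
    action_taken="kept-as-is",
) -> HarmonizedVariant:
    return HarmonizedVariant(
        rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out,
        palindromic, action_taken,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_variants(rng, n=10, scale=0.02):
    """Noisy but well-behaved instrument set for property checks."""
    bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.01, 0.05, n)
    by = 0.4 * bx + rng.normal(0, scale, n)
    return [
        make_variant(f"rs{i}", beta_exp=bx[i], se_exp=0.01, beta_out=by[i], se_out=sy[i])
        for i in range(n)
    ]
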