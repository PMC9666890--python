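import numpy as np
import pytest

from mrkit import SimulationConfig, simulate_study
from mrkit.sumstats import HarmonizedInstrument, SummaryTable, VariantAssociation


def make_variant(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                 beta=0.05, se=0.005, pvalue=1e-10, n=100000):
    return VariantAssociation(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea,
                              other_allele=oa, eaf=eaf, beta=beta, se=se,
                              pvalue=pvalue, n=n)


def make_instrument(rsid="rs1", gamma=0.05, sx=0.005, Gamma=0.01, sy=0.008, **kw):
    return HarmonizedInstrument(rsid=rsid, effect_allele="A", other_allele="G",
                                gamma_hat=gamma, sigma_x=sx,
                                capital_gamma_hat=Gamma, sigma_y=sy, **kw)


@pytest.fixture
def clean_study():
    """55 strong instruments, no pleiotropy, causal effect 0.12."""
    return simulate_study(SimulationConfig(n_snps=55, beta_causal=0.12, seed=101))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
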