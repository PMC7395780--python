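import numpy as np
import pytest

from summr.sumstats import AssociationRecord, harmonized_from_arrays


@pytest.fixture
def make_hs():
    """Factory for harmonized sets from aligned effect arrays."""
    return harmonized_from_arrays


@pytest.fixture
def record_factory():
    def make(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.02,
             se=0.005, eaf=0.3, pval=1e-10, n=100000):
        return AssociationRecord(snp_id=snp_id, effect_allele=effect_allele,
                                 other_allele=other_allele, beta=beta, se=se,
                                 eaf=eaf, pval=pval, n=n)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
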