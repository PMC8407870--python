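import numpy as np
import pytest

from mrnc import GwasRecord, HarmonizedInstrumentSet


def make_record(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02,
                pval=None, n=50_000, **kw):
    return GwasRecord(snp_id=snp, effect_allele=ea, other_allele=oa, eaf=eaf,
                      beta=beta, se=se, pval=pval, n=n, **kw)


def make_hset(gamma, gamma_se, Gamma, Gamma_se, **kw):
    gamma = np.asarray(gamma, dtype=float)
    return HarmonizedInstrumentSet(
        snp_ids=[f"rs{i + 1}" for i in range(len(gamma))],
        exposure_beta=gamma,
        exposure_se=np.asarray(gamma_se, dtype=float),
        outcome_beta=np.asarray(Gamma, dtype=float),
        outcome_se=np.asarray(Gamma_se, dtype=float),
        **kw,
    )


def random_hset(rng, j=6):
    """A well-conditioned random instrument set."""
    gamma = rng.uniform(0.1, 1.0, j) * rng.choice([-1, 1], j)
    return make_hset(
        gamma,
        rng.uniform(0.01, 0.1, j),
        0.3 * gamma + rng.normal(0, 0.05, j),
        rng.uniform(0.01, 0.1, j),
    )


@pytest.fixture
def micro_hset():
    """Two-SNP instrument set with hand-computable IVW solution."""
    return make_hset([0.5, 1.0], [0.02, 0.02], [0.15, 0.25], [0.05, 0.10])
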