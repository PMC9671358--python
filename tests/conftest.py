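import numpy as np
import pytest

from mrkit.harmonize import HarmonizedPair
from mrkit.io import GWASRecord, SummaryDataset
from mrkit.model import MRModel


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.05, se=0.005, pval=1e-10,
                chrom="1", pos=100_000, eaf=0.3, n=218_796, n_cases=None):
    return GWASRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                      beta=beta, se=se, pval=pval, chrom=chrom, pos=pos,
                      eaf=eaf, n=n, n_cases=n_cases)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def three_snp_model():
    """Hand-traceable 3-instrument fixture with exact IVW solution.

    Ratios (-0.22, -0.23, -0.20) with weights (100, 400, 225):
    pooled beta = -159/725 = -0.2193103..., se = 725^-0.5 = 0.0371391.
    """
    return MRModel(
        beta_exposure=[0.10, 0.20, 0.15],
        se_exposure=[0.01, 0.01, 0.01],
        beta_outcome=[-0.022, -0.046, -0.030],
        se_outcome=[0.01, 0.01, 0.01],
        snp_ids=["rs1", "rs2", "rs3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_pairs(rng, k=20, theta=-0.2):
    bx = rng.normal(0.05, 0.02, k)
    bx[np.abs(bx) < 1e-3] = 0.01
    sx = rng.uniform(0.003, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    by = theta * bx + rng.normal(0, 0.005, k)
    return [
        HarmonizedPair(snp_id=f"rs{i}", beta_x=bx[i], se_x=sx[i],
                       eaf_x=0.3, beta_y=by[i], se_y=sy[i], eaf_y=0.3)
        for i in range(k)
    ]


@pytest.fixture
def dataset():
    recs = [
        make_record("rs1", "A", "G", pval=1e-10, chrom="1", pos=100_000, eaf=0.30),
        make_record("rs2", "C", "T", pval=1e-9, chrom="1", pos=200_000, eaf=0.20),
        make_record("rs3", "G", "T", pval=1e-9, chrom="2", pos=100_000, eaf=0.40),
    ]
    return SummaryDataset("exposure", "continuous", recs)
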