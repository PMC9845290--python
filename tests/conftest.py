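import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mrkit.harmonization import HarmonizedRecord, HarmonizedSet
from mrkit.summary_io import SNPAssociation, SummaryDataset


def make_snp(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=0.05, se=0.005,
             pval=1e-10, n=500_000, chrom=None, pos=None):
    return SNPAssociation(rsid, ea, oa, eaf, beta, se, pval, n, chrom, pos)


def make_dataset(snps, label="trait", role="exposure"):
    return SummaryDataset(label, role, {s.rsid: s for s in snps})


def make_harmonized(bx, sx, by, sy):
    """HarmonizedSet straight from effect arrays (alleles are placeholders)."""
    records = [
        HarmonizedRecord(f"rs{i:04d}", "A", "G", float(bx[i]), float(sx[i]),
                         float(by[i]), float(sy[i]), 0.3, 0.3, "aligned")
        for i in range(len(bx))
    ]
    return HarmonizedSet(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def harmonized_strong(rng):
    """30 strong, homogeneous instruments with true causal effect 0.1."""
    L, theta = 30, 0.1
    gamma = rng.normal(0, 0.03, L)
    sx = np.full(L, 0.002)
    sy = np.full(L, 0.0023)
    bx = rng.normal(gamma, sx)
    by = rng.normal(theta * gamma, sy)
    return make_harmonized(bx, sx, by, sy)
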