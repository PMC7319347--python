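import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dsgxe.config import SimulationConfig
from dsgxe.genotypes import GenotypeMatrix
from dsgxe.moderation import synthetic_interaction_fit


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_frame():
    """A 400-subject differential-susceptibility cohort on the model scale."""
    from dsgxe.simulate import simulate_analysis_frame

    cfg = SimulationConfig(n_subjects=400, seed=11)
    return simulate_analysis_frame(cfg)


def make_genotype_matrix(dosages, ref=None, alt=None, subjects=None):
    """GenotypeMatrix from a plain array; SNP ids rs1..rsM, alleles A/G."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    snp_ids = [f"rs{j + 1}" for j in range(m)]
    snps = pd.DataFrame(
        {
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=subjects, columns=snp_ids), snps)


def random_interaction_fit(rng, df=65):
    """A random but valid interaction fit (PSD 2x2 covariance block)."""
    b1 = rng.normal(0, 0.5)
    b3 = rng.normal(0, 0.5)
    while abs(b3) < 0.05:
        b3 = rng.normal(0, 0.5)
    a = rng.normal(0, 0.2, size=(2, 2))
    v = a @ a.T + 1e-4 * np.eye(2)
    return synthetic_interaction_fit(
        b1=b1, b3=b3, v11=v[0, 0], v13=v[0, 1], v33=v[1, 1], df=df
    )
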