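import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refugia.genio import GenotypeMatrix
from refugia.sim import SimConfig, simulate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_variants(n, chrom="chr1", spacing=1000, vclass="OTHER", ancestral="ref"):
    """Uniformly spaced biallelic SNP table for constructed genotype fixtures."""
    pos = np.arange(1, n + 1) * spacing
    anc = {"ref": "A", "alt": "T", "unknown": "."}[ancestral]
    return pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": pos,
        "ref": ["A"] * n,
        "alt": ["T"] * n,
        "ancestral": [anc] * n,
        "vclass": [vclass] * n,
    })


@pytest.fixture(scope="session")
def small_sim():
    """One quick 5x5 expansion reused by IO / integration tests."""
    cfg = SimConfig(seed=11, grid_width=5, grid_height=5, deme_size=40, founders=5,
                    n_chromosomes=2, chrom_length_bp=2_000_000, sample_per_deme=3,
                    post_expansion=60, ancestral_Ne=4000)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def gm_from(dosages, ids=None):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=np.int8))
    if ids is None:
        ids = [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, ids)
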