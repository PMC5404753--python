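import numpy as np
import pytest

from residcog import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with planted convergent effects at gene G1."""
    cfg = SimConfig(
        n_subjects=400,
        n_variants=30,
        n_genes=3,
        n_cpgs_per_region=10,
        ld_block_size=5,
        seed=123,
        planted_effects=[("v0003", 0.4, "snp"), ("cg00006", 0.3, "cpg"), ("G1", 0.3, "rna")],
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
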