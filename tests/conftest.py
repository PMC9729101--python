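import numpy as np
import pytest

from adburden.cohort import GeneSimSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """900-sample cohort, one enriched gene and one null gene."""
    cfg = SimConfig(
        n_eoad=300,
        n_load=300,
        n_control=300,
        genes=[
            GeneSimSpec(
                "RISK1", n_variants=8, maf_range=(0.002, 0.01),
                or_eoad=6.0, or_load=2.5,
            ),
            GeneSimSpec("NULL1", n_variants=8, maf_range=(0.002, 0.01)),
        ],
        seed=13,
    )
    geno, pheno, ann = simulate_cohort(cfg)
    return geno, pheno, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
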