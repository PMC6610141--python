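import logging

import numpy as np
import pytest

from edumr import SimParams, simulate_cohort

# the clamp log line is expected for paper-scale effect sizes; keep test
# output readable
logging.getLogger("edumr.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_params():
    """Fast generator settings: fewer SNPs, no mediation, no confounding."""
    return SimParams(
        n_individuals=4000,
        n_snps_edu=12,
        n_snps_cog=6,
        alpha_CA=0.0,
        confounder_effects=(0.0, 0.0, 0.0),
        n_pcs=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
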