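import numpy as np
import pytest

from strokecea import (
    CohortConfig,
    ModelPipeline,
    MRSDistribution,
    generate_life_table,
    generate_trial_ipd,
    load_parameters,
)

# day-90 mRS distributions at the anchor weighted proportions
# (P(mRS<=1) = 0.693 sublingual, 0.646 injectable)
DAY90_EDSL = (0.370, 0.323, 0.107, 0.080, 0.060, 0.035, 0.025)
DAY90_EDCSI = (0.320, 0.326, 0.120, 0.090, 0.070, 0.040, 0.034)


@pytest.fixture(scope="session")
def day90_pair():
    return MRSDistribution(np.array(DAY90_EDSL)), MRSDistribution(
        np.array(DAY90_EDCSI)
    )


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def default_params():
    return load_parameters()


@pytest.fixture(scope="session")
def model(day90_pair, life_table):
    return ModelPipeline(day90_pair[0], day90_pair[1], life_table)


@pytest.fixture(scope="session")
def cohort_ipd():
    """One moderately sized synthetic trial shared across read-only tests."""
    return generate_trial_ipd(
        CohortConfig(n_per_arm=2000, missing_fraction=0.05, seed=11)
    )
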