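import numpy as np
import pytest

from tmsdecay import (
    CohortConfig,
    DecayParams,
    RatingSeries,
    ScaleSpec,
    generate_cohort,
)

# wide scales for synthetic data that may wander outside clinical ranges
WIDE = ScaleSpec("WIDE", -100.0, 200.0, remission_cutoff=5)
WIDER = ScaleSpec("WIDER", -400.0, 600.0, remission_cutoff=5)


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default 97-patient PHQ-9 cohort."""
    return generate_cohort(CohortConfig(seed=20240501))


@pytest.fixture(scope="session")
def toy_cohort():
    """Two hand-written subjects on a wide scale for oracle comparisons."""
    return [
        RatingSeries("a", [0, 1, 2], [20.0, 14.0, 11.0], WIDE),
        RatingSeries("b", [0, 1, 3], [18.0, 15.0, 9.0], WIDE),
    ]


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Five identical subjects lying exactly on the population curve."""
    cfg = CohortConfig(
        seed=0,
        n_subjects=5,
        sd_amplitude=0.0,
        sd_floor=0.0,
        corr_amplitude_floor=0.0,
        residual_sd=0.0,
        discretize=False,
        retention=1.0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def heterogeneous_noiseless_cohort():
    """Patient-level heterogeneity but no measurement noise (pipeline limit)."""
    cfg = CohortConfig(
        seed=77,
        residual_sd=0.0,
        discretize=False,
        retention=1.0,
        scale=WIDE,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def true_params():
    return DecayParams(amplitude=5.8, time_constant=1.2, floor=11.0)
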