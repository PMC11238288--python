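import numpy as np
import pytest

from rsmpso import (
    GroundTruth,
    PROCESS_FACTORS,
    QuadraticSurface,
    fit_ols,
    load_parsley_dataset,
)


@pytest.fixture(scope="session")
def factors():
    return PROCESS_FACTORS


@pytest.fixture(scope="session")
def chl_table():
    return load_parsley_dataset("chlorophyll")


@pytest.fixture(scope="session")
def aa_table():
    return load_parsley_dataset("ascorbic_acid")


@pytest.fixture(scope="session")
def chl_surface(chl_table):
    return fit_ols(chl_table, order=2)


@pytest.fixture(scope="session")
def aa_surface(aa_table):
    return fit_ols(aa_table, order=2)


@pytest.fixture(scope="session")
def true_surface():
    """A known quadratic in coded units with all ten terms active."""
    return QuadraticSurface(
        b0=7.5,
        linear=np.array([-0.5, -0.3, 0.1]),
        quadratic=np.array([-0.4, -0.55, -0.05]),
        interaction=np.array([0.05, 0.2, 0.6]),
    )


@pytest.fixture(scope="session")
def zero_noise_table(true_surface, factors):
    from rsmpso import generate_ccd_dataset

    truth = GroundTruth(surface=true_surface, noise_sd=0.0, seed=1)
    return generate_ccd_dataset(truth, factors)
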