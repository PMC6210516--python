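import numpy as np
import pytest

from leadgwqr import SyntheticConfig, generate_block_table

COVS = ["building_year", "log_tax", "soil_lead"]


@pytest.fixture(scope="session")
def calibrated_table():
    """Full-size default-calibration table (shared, read-only)."""
    return generate_block_table(SyntheticConfig(n_blocks=1393, seed=0))


@pytest.fixture(scope="session")
def small_table():
    """Small default-calibration table for fast estimator tests."""
    return generate_block_table(SyntheticConfig(n_blocks=150, seed=5))


@pytest.fixture(scope="session")
def uncensored_config():
    """Generator settings for parameter-recovery studies: interior rates
    (no zero inflation, higher intercept) and mild noise, so median
    regression sees the latent linear signal without censoring bias."""
    from leadgwqr.synthetic import DEFAULT_COEFFICIENTS

    coefs = dict(DEFAULT_COEFFICIENTS)
    coefs["intercept"] += 0.40
    return dict(coefficients=coefs, zero_inflation=0.0, noise_scale=0.3)


def design(table):
    X = table[COVS].to_numpy(float)
    y = table["rate"].to_numpy(float)
    coords = table[["u", "v"]].to_numpy(float)
    return X, y, coords
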