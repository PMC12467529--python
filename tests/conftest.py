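import numpy as np
import pytest

from owod import (
    default_catalog,
    default_synthetic_config,
    generate_cohort,
    reference_params,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def ref_params():
    """Eight-feature reference target/acceptable levels."""
    return reference_params()


@pytest.fixture(scope="session")
def small_cohort():
    """Clean synthetic cohort, 300 records per class, fixed seed."""
    cfg = default_synthetic_config(n_per_class=300, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return default_synthetic_config(n_per_class=300, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
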