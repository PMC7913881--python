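import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hcdkin import (  # noqa: E402
    REPORTED_PARAMETERS,
    VelocityDesign,
    generate_velocity_dataset,
    micro_from_macro,
)


@pytest.fixture(scope="session")
def reported_params():
    """The published point estimates at the 99 nM assay load."""
    return REPORTED_PARAMETERS


@pytest.fixture(scope="session")
def default_micro(reported_params):
    """Microscopic rates expanded with the default ratios (4, 100)."""
    return micro_from_macro(reported_params)


@pytest.fixture(scope="session")
def noisy_dataset_seed42(reported_params):
    """The canonical noisy synthetic dataset: extended design, seed 42."""
    return generate_velocity_dataset(
        VelocityDesign(extended=True), reported_params, seed=42
    )


@pytest.fixture(scope="session")
def grid_6x6():
    """A 6x6 concentration grid spanning the assay design (µM)."""
    a = np.geomspace(5.0, 200.0, 6)
    b = np.geomspace(5.0, 150.0, 6)
    return np.array([(x, y) for x in a for y in b])
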