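import logging

import numpy as np
import pytest

from neurofuse.geometry import generate_geometry
from neurofuse.schedule import generate_schedule

logging.getLogger("neurofuse").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return generate_geometry(0)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(1)


@pytest.fixture(scope="session")
def recovery_study():
    """Twenty independently seeded 20-participant cohorts, fully processed
    and fused per condition. Shared across tests: the same runs back the
    parameter-recovery check, the generator's cross-modal calibration
    check, and the ROI-attribution check."""
    from neurofuse.validation import run_recovery_cohort

    return [run_recovery_cohort(seed) for seed in range(1, 21)]


def standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()
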