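import dataclasses

import logging

import pytest

from retphys import OximetryConstants, default_cohort_config
from retphys.synthgen import FAD_CALIBRATION, WT_CALIBRATION

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def constants() -> OximetryConstants:
    return OximetryConstants()


@pytest.fixture
def noiseless_config():
    """Default study-condition config with all measurement degradations off."""
    return default_cohort_config(seed=11).noiseless()


@pytest.fixture
def default_config():
    return default_cohort_config(seed=7)


def scaled_calibrations(n_per_group: int):
    return tuple(
        dataclasses.replace(c, n_animals=n_per_group)
        for c in (WT_CALIBRATION, FAD_CALIBRATION)
    )
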