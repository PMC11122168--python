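import copy

import pytest

from metsdx.cohort import SubjectRecord
from metsdx.simulate import (calibrated_default_config, default_config,
                             simulate_cohort)


@pytest.fixture
def make_record():
    """Factory for valid subject records with overridable fields."""

    def factory(**overrides):
        base = dict(
            id="S1", sex="female", age=45.0, body_weight=110.0, height=160.0,
            waist=120.0, hip=130.0, sbp=125.0, dbp=80.0, glucose=95.0,
            total_chol=190.0, hdl=55.0, triglycerides=120.0,
        )
        base.update(overrides)
        return SubjectRecord(**base)

    return factory


@pytest.fixture(scope="session")
def big_sim():
    """One 20,000-subject draw from the default conditions, shared across
    marginal-recovery checks."""
    config = default_config()
    config.n = 20000
    cohort, report = simulate_cohort(config, seed=123)
    return config, cohort, report


@pytest.fixture(scope="session")
def calibrated_cohort():
    """The default cohort (n = 1912) after prevalence calibration, with the
    config that produced it."""
    config = calibrated_default_config(seed=7)
    cohort, report = simulate_cohort(config, seed=7)
    return config, cohort, report
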