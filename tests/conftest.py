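import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfastk.params import load_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=15, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pfos_monkey():
    physio, chem, meta = load_fixture("pfos_monkey")
    return physio, chem


@pytest.fixture(scope="session")
def pfoa_human():
    physio, chem, meta = load_fixture("pfoa_human")
    return physio, chem


@pytest.fixture(scope="session")
def pfos_human():
    physio, chem, meta = load_fixture("pfos_human")
    return physio, chem


@pytest.fixture(scope="session")
def pfhxs_human():
    physio, chem, meta = load_fixture("pfhxs_human")
    return physio, chem


@pytest.fixture(scope="session")
def small_design():
    """A reduced primate design for tests where runtime matters more than
    statistical power: two oral groups at 4 weeks plus an IV washout."""
    from pfastk.synth import GroupDesign, StudyDesign
    oral_obs = tuple(168.0 * w for w in (1, 2, 3, 4, 5, 6, 8))
    iv_obs = (1.0, 24.0, 168.0, 672.0, 1344.0)
    groups = (
        GroupDesign("oral_low", "oral", 0.03, "daily", 4.0, oral_obs),
        GroupDesign("oral_high", "oral", 0.75, "daily", 4.0, oral_obs),
        GroupDesign("iv", "iv", 2.0, "single", 0.0, iv_obs),
    )
    return StudyDesign(groups=groups, n_subjects=3, residual_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)
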