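import numpy as np
import pytest

from nutriopt.params import generate_synthetic_fixture


@pytest.fixture(scope="session")
def draw_hb():
    """High-burden synthetic parameter set used across the suite."""
    return generate_synthetic_fixture(1, "high-burden")


@pytest.fixture(scope="session")
def draw_toy():
    """Toy profile with uniform exposures and closed-form-checkable values."""
    return generate_synthetic_fixture(1, "toy")


@pytest.fixture(scope="session")
def birth_arrays(draw_hb):
    """A deterministic synthetic birth cohort for child-simulation tests."""
    j = draw_hb.ga_bw_joint
    rng = np.random.default_rng(2024)
    n = 10_000
    sex = (rng.random(n) > draw_hb.demography.infant_sex_ratio).astype(int)
    ga = j.ga_mean + j.ga_sd * rng.standard_normal(n)
    bw = (
        j.bw_mean
        + j.corr * j.bw_sd * (ga - j.ga_mean) / j.ga_sd
        + j.bw_sd * np.sqrt(1 - j.corr**2) * rng.standard_normal(n)
    )
    return sex, ga, bw
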