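import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import octogrowth as og

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def gompertz_all():
    """Whole-cohort Gompertz curve (inflection weight 63.11 g)."""
    return og.GrowthParams(model="gompertz", m_inf=63.11 * np.e, gamma=9.81, g1=0.0137)


@pytest.fixture
def small_cohort():
    """A small default-parameter synthetic cohort, fixed seed."""
    spec = og.CohortSpec(n_specimens=250, seed=7)
    return spec, og.generate_cohort(spec)


def gompertz_data(params, n, noise_cv, seed, age_range=(85.0, 313.0)):
    """Shared helper: (age, mass) draws around a Gompertz curve."""
    r = np.random.default_rng(seed)
    ages = r.uniform(*age_range, size=n)
    m = np.asarray(og.predict_mass(params, ages), dtype=float)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        m = m * np.exp(r.normal(-0.5 * sigma**2, sigma, size=n))
    return ages, m
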