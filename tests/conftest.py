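import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eismon as em

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def reference_params() -> em.CircuitParams:
    """A typical interfacial parameter set used across fitting tests."""
    return em.CircuitParams(rsol=100.0, rct=5000.0, q=2e-5, n=0.85)


@pytest.fixture
def freq_grid() -> np.ndarray:
    return em.log_frequency_grid(1.0, 1e6, 10)


@pytest.fixture
def clean_spectrum(reference_params, freq_grid) -> em.Spectrum:
    return em.simulate_spectrum(reference_params, freq_grid)


@pytest.fixture
def short_rich_series() -> tuple[em.GrowthScenario, em.MonitoringSeries]:
    """A coarse auxin-rich series (43 spectra at 4 h) with 1% noise, seeded."""
    scenario = em.scenario_preset("auxin_rich", seed=42, spectrum_interval=4.0)
    return scenario, em.simulate_series(scenario)
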