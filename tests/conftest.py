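import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pepperqams import (
    NoiseSpec,
    PeakShapeSpec,
    simulate_chromatogram,
)
from pepperqams.presets import (
    PEAK_SIGMA_MIN,
    RETENTION_MIN,
    reference_response_models,
)

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def responses():
    return reference_response_models()


@pytest.fixture()
def five_peak_specs():
    """The standard mix: five well-separated peaks at their nominal times."""
    areas = {"HeSS": 2.0e5, "HaSS": 6.0e5, "HbSS": 2.5e5, "Nonivamide": 4.0e5, "HgSS": 2.2e5}
    return [
        PeakShapeSpec(name, RETENTION_MIN[name], areas[name], sigma=PEAK_SIGMA_MIN[name])
        for name in areas
    ]


@pytest.fixture()
def five_peak_chromatogram(five_peak_specs):
    return simulate_chromatogram(
        five_peak_specs,
        duration=50.0,
        sampling_rate=20.0,
        noise=NoiseSpec(baseline_sigma=0.3, seed=7),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
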