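import pytest
from hypothesis import HealthCheck, settings

import qamskit as qk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_bundle():
    """A deterministic noiseless study with the published detector truth."""
    truth = qk.default_study_truth(seed=11, noise_cv=0.0)
    return qk.generate_study(truth)


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_bundle):
    return qk.fit_panel(noiseless_bundle.calibration_series)


@pytest.fixture(scope="session")
def proportional_bundle():
    """Noiseless study with zero intercepts (proportional detector)."""
    truth = qk.default_study_truth(seed=5, noise_cv=0.0, zero_intercepts=True)
    return qk.generate_study(truth)
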