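import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import minmod as mm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def normal_params():
    return mm.NORMAL_SUBJECT


@pytest.fixture(scope="session")
def clean_record(normal_params):
    """Noiseless IVGTT at the normal-subject fixture."""
    return mm.generate_ivgtt(normal_params, noise_cv=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_fit(clean_record):
    return mm.fit_minimal_model(clean_record)


@pytest.fixture(scope="session")
def insulin_template():
    return mm.InsulinCurveTemplate()


@pytest.fixture(scope="session")
def template_input(insulin_template):
    """Per-minute sampled template insulin as a model input."""
    t = np.arange(-10.0, 181.0)
    return mm.InsulinInput(t, np.asarray(insulin_template(t)))
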