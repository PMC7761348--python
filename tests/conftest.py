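import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20201124)


@pytest.fixture
def flat_phantom():
    """Noise-free phantom with every joint at target ratio 1.0."""
    from scintiquant.phantom import PhantomSpec, render_phantom

    return render_phantom(PhantomSpec(patient_id="flat", seed=0))
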