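import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hour_recording():
    """One hour of default-parameter synthetic EEG with ground truth."""
    from swdkit.simulate import EEGSimParams, generate_eeg

    return generate_eeg(EEGSimParams(duration=3600.0, seed=1))
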