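import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240422)


@pytest.fixture
def small_registry(tmp_path):
    """A tiny hand-written registry CSV with known content."""
    path = tmp_path / "registry.csv"
    path.write_text(
        "patient_id,gender,icd_code,age_at_event\n"
        "P1,M,I67.1,56\n"
        "P1,M,I10,56\n"
        "P1,M,E78.0,63\n"
        "P2,W,I67.1,45\n"
        "P2,W,R51.8,45\n"
        "P3,W,I10,47\n"
    )
    return path
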