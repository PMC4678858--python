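import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from crabreap.construct_digest import extract_amplicon
from crabreap.pipeline import build_constructs


@pytest.fixture(scope="session")
def constructs():
    """Assembled lesion (O4-EtdT), control and synthetic competitor constructs."""
    lesion, control, competitor = build_constructs("Et")
    return {"lesion": lesion, "control": control, "competitor": competitor}


@pytest.fixture(scope="session")
def control_duplex(constructs):
    return extract_amplicon(constructs["control"])


@pytest.fixture(scope="session")
def competitor_duplex(constructs):
    return extract_amplicon(constructs["competitor"])


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
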