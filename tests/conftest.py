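import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One small two-condition study with planted truth, shared by tests."""
    from chromascreen.synthetic_data import make_study_fixture

    root = tmp_path_factory.mktemp("study")
    manifest, truth = make_study_fixture(root, seed=11, scale="small")
    return root, manifest, truth
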