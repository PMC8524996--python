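import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cadeval import StudyConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic study (59 malignant + 253 normal, 18 readers)."""
    return generate_study(StudyConfig(seed=20211018))


@pytest.fixture()
def small_config():
    """A fast-running study for structural tests."""
    from cadeval import GroupConfig, SwitchProbs

    switch = SwitchProbs(fn_to_tp=0.6, fp_to_tn=0.4, tp_to_fn=0.02, tn_to_fp=0.2)
    return StudyConfig(
        n_malignant=12,
        n_normal=30,
        groups=(
            GroupConfig("general_physician", 2, 0.47, 0.96, switch),
            GroupConfig("radiologist", 2, 0.51, 0.96, switch),
        ),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
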