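import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """One small generated dataset per architecture (with outliers where
    the architecture has an outlier class)."""
    from cellink.synthetic import STUDY_N, OUTLIER_CLASS, generate_dataset

    bundles = {}
    for i, label in enumerate(STUDY_N):
        bundles[label] = generate_dataset(
            label, 12, seed=100 + i, n_outliers=3 if label in OUTLIER_CLASS else 0
        )
    return bundles
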