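import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pvsignal.datasets import load_antibody_attributes, load_antibody_counts, reference_model

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_counts() -> pd.DataFrame:
    """Packaged per-antibody IR counts with the published ROR/CI/signal."""
    return load_antibody_counts()


@pytest.fixture(scope="session")
def reference_attributes() -> pd.DataFrame:
    return load_antibody_attributes()


@pytest.fixture(scope="session")
def reference_results():
    """Fitted screen over the packaged 25-antibody universe."""
    return reference_model().fit()
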