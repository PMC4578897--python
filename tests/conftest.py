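import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ceramides():
    from lipidlux.fixtures import ceramide_scan

    return ceramide_scan()


@pytest.fixture(scope="session")
def ceramide_smiles(ceramides):
    return [sp.smiles for sp in ceramides]


@pytest.fixture(scope="session")
def pi_set():
    from lipidlux.fixtures import pi_series

    return pi_series()
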