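import pytest
from hypothesis import HealthCheck, settings

from cpma import io as cpma_io

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    """The bundled 47-SNP x 7-disease association matrix."""
    return cpma_io.load_fixture_table2()


@pytest.fixture(scope="session")
def table2_frame():
    """Raw fixture table including the printed CPMA p-value column."""
    return cpma_io.fixture_table2_frame()
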