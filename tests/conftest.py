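import pytest

from shuntpred.pipeline import AnalysisConfig
from shuntpred.synthetic import canonical_fixture, default_config, simulate_cohort


@pytest.fixture(scope="session")
def fixture_and_report():
    """Canonical fixture cohort reconstructed from the printed group tables,
    together with the solver report (shared across the suite)."""
    return canonical_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_and_report):
    return fixture_and_report[0]


@pytest.fixture(scope="session")
def reconstruction_report(fixture_and_report):
    return fixture_and_report[1]


@pytest.fixture(scope="session")
def pinned_config():
    """Analysis config with the reference callosal-angle cutoff pinned."""
    return AnalysisConfig(ca_cutoff=68.7)


@pytest.fixture(scope="session")
def simulated_cohort():
    return simulate_cohort(default_config(seed=42))
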