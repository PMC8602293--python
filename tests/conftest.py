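import pytest
from hypothesis import HealthCheck, settings

from irdsolve.fixture import build_reference_fixture
from irdsolve.pipeline import run_pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return build_reference_fixture()


@pytest.fixture(scope="session")
def fixture_result(bundle):
    return run_pipeline(bundle.cases, bundle.panel, bundle.repeat_ranges)


@pytest.fixture(scope="session")
def cases_by_id(bundle):
    return {c.case_id: c for c in bundle.cases}


@pytest.fixture(scope="session")
def resolutions_by_id(fixture_result):
    return {r.case_id: r for r in fixture_result.resolutions}
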