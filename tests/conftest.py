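import pytest

from stereofid.conversion import ConversionPolicy
from stereofid.fixtures import build_fixture_set, oracle_suite
from stereofid.report import run_dataset

FIXTURE_SEED = 7
RUN_SEED = 42


@pytest.fixture(scope="session")
def fixture_set():
    return build_fixture_set(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_records(fixture_set):
    return {spec.fixture_id: record for record, spec in fixture_set}


@pytest.fixture(scope="session")
def fixture_specs(fixture_set):
    return {spec.fixture_id: spec for _, spec in fixture_set}


@pytest.fixture(scope="session")
def oracle_results():
    return oracle_suite(FIXTURE_SEED)


@pytest.fixture(scope="session")
def pipeline_artifacts(fixture_set):
    """One full pipeline run shared by the conversion/report/acceptance tests.

    Salts are kept whole (no stripping) so that every screened fixture can be
    followed cpd -> mm under the identity-preserving policy.
    """
    records = [record for record, _ in fixture_set]
    policy = ConversionPolicy(
        constrain_chirality=True,
        undefined_center_policy="preserve_undefined",
        strip_salts_at_wash=False,
    )
    return run_dataset(records, policy, seed=RUN_SEED)
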