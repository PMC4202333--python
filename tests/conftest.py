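import pytest
from hypothesis import HealthCheck, settings

import cytonuclear as cn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_records():
    return cn.generate_table1_fixture()


@pytest.fixture(scope="session")
def table1_flags(table1_records):
    return cn.assign_category_flags(table1_records)


@pytest.fixture(scope="session")
def table1_summary(table1_records, table1_flags):
    return cn.summarize_counts(table1_records, table1_flags)
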