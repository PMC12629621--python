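import pytest

from psaguide import default_rules, generate_cohort, load_table1_fixture
from psaguide.rag import MockGuidelineBackend, PipelineConfig, default_index


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def cohort():
    """Default 44-case synthetic cohort, seed 0."""
    return generate_cohort()


@pytest.fixture(scope="session")
def index():
    return default_index()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def mock_pipeline(index):
    return PipelineConfig(backend=MockGuidelineBackend(), index=index)
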