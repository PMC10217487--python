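import pytest

from cllburden.context import default_context, run_both_scenarios
from cllburden.params import BaselineParameters
from cllburden.registry import default_registry
from cllburden.synthetic import small_validation_contexts


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def params():
    return BaselineParameters()


@pytest.fixture(scope="session")
def default_ctx():
    return default_context()


@pytest.fixture(scope="session")
def both_results(default_ctx):
    """Fixed and continuous scenario results plus the difference report
    on the shipped default configuration (shared across tests)."""
    return run_both_scenarios(default_ctx)


@pytest.fixture(scope="session")
def small_ctxs():
    return small_validation_contexts()
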