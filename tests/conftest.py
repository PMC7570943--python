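import pytest

from coxqsar import (
    load_external_validation,
    load_internal_validation,
    load_reference_models,
    load_training_table,
)


@pytest.fixture(scope="session")
def training_table():
    return load_training_table()


@pytest.fixture(scope="session")
def internal_table():
    return load_internal_validation()


@pytest.fixture(scope="session")
def external_table():
    return load_external_validation()


@pytest.fixture(scope="session")
def reference_models():
    """The four published prediction equations (printed 4-dp coefficients)."""
    return load_reference_models()
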