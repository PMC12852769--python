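import pytest

from metalrisk import load_reference_bundle, load_study_records


@pytest.fixture(scope="session")
def bundle():
    """(tox table, exposure params, LOD table) packaged defaults."""
    return load_reference_bundle()


@pytest.fixture(scope="session")
def tox(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def params(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def lod_table(bundle):
    return bundle[2]


@pytest.fixture(scope="session")
def study_records():
    """The 80 packaged group-summary records."""
    return load_study_records()
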