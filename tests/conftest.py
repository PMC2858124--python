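import pytest

from evita import fixture_path, load_dossier


@pytest.fixture(scope="session")
def dossiers():
    """All bundled worked-example dossiers, keyed by fixture name."""
    from evita import FIXTURE_NAMES

    return {name: load_dossier(fixture_path(name)) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def lenalidomide(dossiers):
    return dossiers["lenalidomide_mm"]


@pytest.fixture(scope="session")
def bupropion(dossiers):
    return dossiers["bupropion_depression"]
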