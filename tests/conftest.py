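import pytest

from paleodiet import isodata, pipeline


@pytest.fixture(scope="session")
def plants():
    return isodata.load_plants()


@pytest.fixture(scope="session")
def fauna():
    return isodata.load_fauna()


@pytest.fixture(scope="session")
def humans():
    return isodata.load_humans()


@pytest.fixture(scope="session")
def study():
    """Packaged tables pushed through QC with the standing exclusions."""
    return pipeline.load_study()
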