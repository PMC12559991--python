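import pytest

from svtether import control_model


@pytest.fixture(scope="session")
def model():
    """Control model (nine copies per species, repulsion on).

    Fine- and simulation-grid tables are built lazily and cached on the
    instance, so the first test touching each grid pays its cost once.
    """
    return control_model()
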