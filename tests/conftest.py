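import pytest

from myoarch import io as mio
from myoarch.architecture import derive_architecture
from myoarch.morphospace import assemble_morphospace


@pytest.fixture(scope="session")
def table2():
    """The bundled bat architecture table with its printed derived columns."""
    return mio.load_table2()


@pytest.fixture(scope="session")
def table2_records():
    return mio.table2_records()


@pytest.fixture(scope="session")
def fixture_specimen():
    return mio.load_fixture_specimen()


@pytest.fixture(scope="session")
def bat_architecture(table2_records):
    """Derived architecture for the 18 fibre-length-bearing fixture muscles."""
    return derive_architecture(table2_records)


@pytest.fixture(scope="session")
def bat_morphospace(bat_architecture, fixture_specimen):
    return assemble_morphospace(bat_architecture, [fixture_specimen])
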