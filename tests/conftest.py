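import pytest
from hypothesis import HealthCheck, settings

from adsorbscreen.reference import (
    eda_records,
    load_reference_tables,
    nbo_rows,
    thermo_records,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: the six pharmaceutical complexes in published adsorption order
PUBLISHED_ORDER = ["AMOX-CS", "AMOX-GO-1", "AMOX-GO-2", "IBU-CS", "IBU-GO-2", "IBU-GO-1"]


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def reference_thermo(reference_tables):
    return thermo_records(reference_tables)


@pytest.fixture(scope="session")
def reference_eda(reference_tables):
    return eda_records(reference_tables)


@pytest.fixture(scope="session")
def reference_nbo(reference_tables):
    return nbo_rows(reference_tables)
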