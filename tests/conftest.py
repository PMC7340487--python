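import pandas as pd
import pytest

from sdgattain import load_registry
from sdgattain.registry import registry_index


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def defs(registry):
    return registry_index(registry)


@pytest.fixture()
def small_panel(registry):
    """Three well-formed records across two indicators and two locations."""
    return pd.DataFrame({
        "location_id": ["China", "China", "Beijing"],
        "region": ["national", "national", "eastern"],
        "indicator_id": ["3.2.1", "3.2.1", "3.1.2"],
        "sex": ["both", "both", "both"],
        "year": [2015, 2016, 2016],
        "value": [10.5, 10.2, 0.96],
    })
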