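import numpy as np
import pandas as pd
import pytest

from ecowarn import (
    GreySeries,
    IndicatorPanel,
    IndicatorRegistry,
    IndicatorSpec,
    default_registry,
    load_fixture,
)

# Worked-example composite series (first value plus the constant vector Y)
WE_X0 = np.array([0.1893, 0.2905, 0.3505, 0.5768, 0.7200, 0.7774, 0.8047, 0.8771])
WE_X1 = np.array([0.1893, 0.4798, 0.8303, 1.4071, 2.1271, 2.9045, 3.7092, 4.5863])
WE_FITTED = np.array([0.1893, 0.3879, 0.4507, 0.5238, 0.6087, 0.7073, 0.8220, 0.9552])
WE_A = -0.150207
WE_B = 0.33103771
WE_C1 = 2.3931768
WE_C0 = -2.2038768
WE_MULT = 0.359472
WE_CRATIO = 0.3788

#: published mean relative fitting errors (%), per county
COUNTY_REL_ERR = {"MH": 3.8, "PA": 2.6, "HZ": 2.4, "XH": 1.6, "HL": 4.7, "LD": 5.5, "HZh": 5.8}


@pytest.fixture(scope="session")
def registry() -> IndicatorRegistry:
    return default_registry()


@pytest.fixture(scope="session")
def mini_registry() -> IndicatorRegistry:
    return IndicatorRegistry(
        [
            IndicatorSpec("pos_a", "positive indicator A", "P", "positive"),
            IndicatorSpec("pos_b", "positive indicator B", "P", "positive"),
            IndicatorSpec("neg_a", "negative indicator A", "E", "negative"),
        ]
    )


@pytest.fixture
def mini_panel(mini_registry) -> IndicatorPanel:
    regions = ["north", "south"]
    years = [2011, 2012, 2013, 2014]
    index = pd.MultiIndex.from_product([regions, years], names=["region", "year"])
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.uniform(1.0, 9.0, size=(len(index), 3)), index=index, columns=mini_registry.codes
    )
    return IndicatorPanel(data)


@pytest.fixture(scope="session")
def we_series() -> GreySeries:
    return GreySeries(values=WE_X0, years=list(range(2011, 2019)))


@pytest.fixture(scope="session")
def county_table() -> pd.DataFrame:
    return load_fixture("table5_ewv")
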