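import pandas as pd
import pytest

from heatbudget import budget as bd
from heatbudget import scenarios as sc
from heatbudget import synthgen as sg


@pytest.fixture(scope="session")
def may_series():
    """Synthetic early-summer session, fixed seed, 720 records at 10 s."""
    return sg.generate(sg.may_session_spec(seed=123))


@pytest.fixture(scope="session")
def october_series():
    return sg.generate(sg.october_session_spec(seed=123))


@pytest.fixture(scope="session")
def personas():
    profiles, sites, scales = sc.study_defaults()
    return profiles, sites, scales


@pytest.fixture
def may_mean_record():
    """One record at the early-summer session mean conditions, turf at 60 °C."""
    return bd.MicrometRecord(
        timestamp=pd.Timestamp("2020-05-19T19:30:00"),
        ta_c=33.3,
        rh_pct=48.0,
        ws_ms=2.4,
        sr_wm2=886.8,
        tg_c=40.0,
        ts_c=60.0,
    )
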