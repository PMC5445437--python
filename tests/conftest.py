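import numpy as np
import pandas as pd
import pytest

from cardioauto import synthetic_data as sd
from cardioauto.beat_io import BeatSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Low-noise generator settings for parameter-recovery tests."""
    return sd.SynthConfig(seed=0, day_minutes=3.0, rr_noise_sd=0.2,
                          rsa_amp=0.2, sbp_noise_sd=0.2)


def make_regular_series(n=60, rr=180.0, pr=45.0, sbp=125.0, dbp=85.0,
                        animal_id="r01", day_label="baseline", group="control"):
    """Hand-built perfectly regular conducted train for rule tests."""
    t_r = rr * np.arange(1, n + 1)
    df = pd.DataFrame({
        "t_P": t_r - pr,
        "t_R": t_r,
        "t_S": t_r + 15.0,
        "t_Tpeak": t_r + 45.0,
        "t_Tend": t_r + 60.0,
        "conducted": True,
        "SBP": float(sbp),
        "DBP": float(dbp),
    })
    return BeatSeries(beats=df, animal_id=animal_id, day_label=day_label, group=group)


@pytest.fixture
def regular_series():
    return make_regular_series()
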