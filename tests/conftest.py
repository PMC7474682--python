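import numpy as np
import pandas as pd
import pytest

from dielflux import (
    ChamberSpec,
    LakeConfig,
    MetParams,
    default_scenario,
    render_sensor_records,
    simulate_flux_truth,
    simulate_met,
)
from dielflux.pipeline import build_all_cycles

#: met forcing with constant T/P (needed for exact flux round-trips)
CONSTANT_MET = MetParams(
    wind_noise_sd=0.0,
    pressure_step_sd=0.0,
    air_temp_diel_amp=0.0,
    water_temp_diel_amp=0.0,
    cloud_factor_range=(1.0, 1.0),
)


def make_noiseless_scenario(**overrides):
    defaults = dict(
        rng_seed=7,
        n_days=3,
        flux_noise_sigma=0.0,
        ebullition_rate=0.0,
        sensor_noise_sd=0.0,
        ambient_sigma=0.0,
        met=CONSTANT_MET,
    )
    defaults.update(overrides)
    return default_scenario(**defaults)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noiseless square-wave scenario rendered end to end (shared, read-only)."""
    scenario = make_noiseless_scenario()
    cycles = build_all_cycles(scenario)
    truth = simulate_flux_truth(scenario, cycles)
    met = simulate_met(scenario, cycles)
    series = render_sensor_records(truth, scenario, met)
    return {
        "scenario": scenario,
        "cycles": cycles,
        "truth": truth,
        "met": met,
        "series": series,
    }


@pytest.fixture()
def one_lake():
    return LakeConfig(
        lake_id="L1",
        latitude=58.0,
        longitude=15.0,
        utc_offset=1.0,
        season_label="mixing",
        chambers=(ChamberSpec("L1-C1", 1.0, 0.03, 0.1),),
    )


def simple_series_df(timestamps, ppm=None, raw=None, rh=60.0, temp=15.0, state="closed"):
    n = len(timestamps)
    data = {
        "timestamp": pd.DatetimeIndex(timestamps),
        "rh_pct": np.broadcast_to(np.asarray(rh, dtype=float), n).copy(),
        "temp_c": np.broadcast_to(np.asarray(temp, dtype=float), n).copy(),
        "state": np.broadcast_to(np.asarray(state), n).copy(),
    }
    if ppm is not None:
        data["ch4_ppm"] = np.asarray(ppm, dtype=float)
    if raw is not None:
        data["raw_signal"] = np.asarray(raw, dtype=float)
    return pd.DataFrame(data)
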