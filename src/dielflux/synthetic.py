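"""Synthetic chamber-sensor records and meteorological forcing.

Generates minute-resolution flux ground truth with a multiplicative
day/night pattern (configurable day:night ratio), lognormal AR(1) noise and
episodic ebullition step events, then renders the automated/manual chamber
measurement process (closure cycles, flushing, raw-sensor signal through an
invertible calibration model) so the full pipeline can be exercised and
checked against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chamber import ChamberSpec, ClosureSeries, CalibrationModel, absolute_humidity, R_GAS
from .solar import DielCycle

_MINUTE = pd.Timedelta(minutes=1)
_HOUR = pd.Timedelta(hours=1)


@dataclass(frozen=True)
class LakeConfig:
    """One lake: location, season label and its chambers."""

    lake_id: str
    latitude: float
    longitude: float
    utc_offset: float
    season_label: str = "stratified"  # "stratified" | "mixing"
    chambers: tuple[ChamberSpec, ...] = ()

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.lake_id}: latitude out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.lake_id}: longitude out of range")
        if not self.chambers:
            raise ValueError(f"{self.lake_id}: at least one chamber required")
        if self.season_label not in ("stratified", "mixing"):
            raise ValueError(f"{self.lake_id}: season_label must be stratified|mixing")
        object.__setattr__(self, "chambers", tuple(self.chambers))


@dataclass(frozen=True)
class MetParams:
    """Meteorological forcing parameters (defaults give realistic magnitudes)."""

    wind_mean: float = 3.0  # m s-1
    wind_diel_amp: float = 1.5  # sinusoid amplitude, peak early afternoon
    wind_peak_local_hour: float = 14.0
    wind_ar1_phi: float = 0.7
    wind_noise_sd: float = 0.5
    par_peak: float = 1200.0  # umol m-2 s-1 clear-sky midday
    cloud_factor_range: tuple[float, float] = (0.6, 1.0)  # per-day uniform
    pressure_mean: float = 1013.0  # hPa
    pressure_step_sd: float = 0.15  # hPa per hour random walk
    frontal_events: tuple[tuple[str, float, float], ...] = ()  # (start, slope hPa/h, hours)
    air_temp_mean: float = 12.0
    air_temp_diel_amp: float = 4.0
    air_temp_peak_local_hour: float = 15.0
    water_temp_mean: float = 14.0
    water_temp_diel_amp: float = 0.03  # keeps day:night ratio within ~[0.997, 1.006]
    headspace_temp_offset: float = 1.0  # chamber headspace above air temp


@dataclass(frozen=True)
class SimScenario:
    """Full generative scenario with known ground truth."""

    lakes: tuple[LakeConfig, ...]
    n_days: int = 30
    r_true: float = 2.5
    base_flux: float = 30.0  # umol m-2 h-1
    flux_noise_sigma: float = 0.3  # log-scale SD
    ebullition_rate: float = 0.2  # events chamber-1 day-1
    ebullition_mean_size: float = 15.0  # umol m-2
    ambient_ch4: float = 1.9  # ppm
    ambient_sigma: float = 0.05  # ppm, slow AR(1) background variation
    ar1_phi: float = 0.6  # hourly log-noise autocorrelation
    ramp_minutes: float = 0.0  # half-sine day/night transition width (0 = square)
    sensor_noise_sd: float = 0.2  # raw-signal units, additive white noise
    manual_noise_ppm: float = 0.0
    cal_beta0: float = 0.5  # ppm
    cal_beta1: float = 0.02  # ppm per raw unit
    cal_beta2: float = 0.02  # ppm per g m-3
    start_date: str = "2017-09-01"
    rng_seed: int = 0
    met: MetParams = field(default_factory=MetParams)

    def __post_init__(self) -> None:
        if self.r_true <= 0:
            raise ValueError("r_true must be positive")
        if self.base_flux <= 0:
            raise ValueError("base_flux must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("flux_noise_sigma", "ebullition_rate", "ebullition_mean_size",
                     "sensor_noise_sd", "ambient_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cal_beta1 <= 0:
            raise ValueError("cal_beta1 must be positive")
        object.__setattr__(self, "lakes", tuple(self.lakes))

    def lake(self, lake_id: str) -> LakeConfig:
        for lk in self.lakes:
            if lk.lake_id == lake_id:
                return lk
        raise KeyError(lake_id)

    def chamber(self, chamber_id: str) -> tuple[LakeConfig, ChamberSpec]:
        for lk in self.lakes:
            for ch in lk.chambers:
                if ch.chamber_id == chamber_id:
                    return lk, ch
        raise KeyError(chamber_id)

    @property
    def true_calibration(self) -> CalibrationModel:
        return CalibrationModel(self.cal_beta0, self.cal_beta1, self.cal_beta2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lakes"] = [
            {**asdict(lk), "chambers": [asdict(c) for c in lk.chambers]}
            for lk in self.lakes
        ]
        return d


@dataclass
class TruthTable:
    """Minute-resolution true flux per chamber, diffusive/ebullitive split.

    ``data`` columns: lake_id, chamber_id, timestamp, diffusive_flux
    [umol m-2 h-1], ebullition_umol_m2 (event amount landing in that minute,
    zero elsewhere).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.data["diffusive_flux"]).all():
            raise ValueError("true flux must be finite")
        if (self.data["ebullition_umol_m2"] < 0).any():
            raise ValueError("ebullitive component must be non-negative")

    def chamber_slice(self, chamber_id: str) -> pd.DataFrame:
        return self.data[self.data["chamber_id"] == chamber_id]

    def interval_mean_flux(
        self, chamber_id: str, t0: pd.Timestamp, t1: pd.Timestamp
    ) -> float:
        """True mean flux over [t0, t1]: diffusive mean + ebullition / duration."""
        t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
        df = self.chamber_slice(chamber_id)
        sel = df[(df["timestamp"] >= t0) & (df["timestamp"] <= t1)]
        if sel.empty:
            raise ValueError(f"no truth for {chamber_id} in {t0}..{t1}")
        duration_h = (t1 - t0) / _HOUR
        diffusive = _interval_diffusive_mean(sel, t0, t1)
        ebul = float(sel.loc[sel["timestamp"] > t0, "ebullition_umol_m2"].sum())
        return diffusive + ebul / duration_h


def _interval_diffusive_mean(sel: pd.DataFrame, t0: pd.Timestamp, t1: pd.Timestamp) -> float:
    """Trapezoid-free mean of a step-held minute series over [t0, t1]."""
    # values are step-held over [t, t+1min); last point weights the remainder
    ts = sel["timestamp"].to_numpy()
    f = sel["diffusive_flux"].to_numpy(dtype=float)
    edges = np.append(ts, np.datetime64(t1))
    w = np.diff(edges).astype("timedelta64[s]").astype(float)
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:
        return float(f[-1])
    return float(np.average(f, weights=np.maximum(w, 1e-12)))


def _chamber_rng(scenario: SimScenario, lake_idx: int, chamber_idx: int, stream: int):
    return np.random.default_rng(
        [scenario.rng_seed, 1000 + lake_idx, 2000 + chamber_idx, stream]
    )


def _day_modulation(
    minutes: pd.DatetimeIndex, cycles: list[DielCycle], r: float, ramp_minutes: float
) -> np.ndarray:
    """Multiplier m(t): r during daylight, 1 at night, optional half-sine ramps."""
    t = minutes.values
    m = np.ones(len(minutes), dtype=float)
    for c in cycles:
        day = (t >= np.datetime64(c.t_sunrise)) & (t < np.datetime64(c.t_sunset))
        m[day] = r
    if ramp_minutes > 0:
        w = ramp_minutes * 60.0  # seconds
        events = []
        for c in cycles:
            events.append((c.t_sunrise, True))
            events.append((c.t_sunset, False))
        for event, rising in events:
            dt_s = (t - np.datetime64(event)).astype("timedelta64[s]").astype(float)
            in_ramp = np.abs(dt_s) <= w / 2
            frac = 0.5 * (1.0 + np.sin(math.pi * dt_s[in_ramp] / w))
            if not rising:
                frac = 1.0 - frac
            m[in_ramp] = 1.0 + (r - 1.0) * frac
    return m


def _stationary_ar1(n: int, phi: float, rng) -> np.ndarray:
    """Unit-variance stationary AR(1) path of length n."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1.0 - phi * phi) if n > 1 else []
    for i in range(1, n):
        z[i] = phi * z[i - 1] + innov[i - 1]
    return z


def simulate_flux_truth(
    scenario: SimScenario, cycles: dict[str, list[DielCycle]]
) -> TruthTable:
    """Minute-resolution ground-truth fluxes for every chamber.

    Diffusive truth: F(t) = base_flux * m(t) * exp(sigma * Z(t)) with m(t)
    the day/night modulation and Z a stationary unit-variance AR(1) held at
    hourly steps.  Ebullition events arrive as a Poisson process per chamber
    with exponential sizes and land in the minute containing them.
    """
    frames = []
    for li, lake in enumerate(scenario.lakes):
        lake_cycles = cycles[lake.lake_id]
        if not lake_cycles:
            raise ValueError(f"no diel cycles supplied for lake {lake.lake_id}")
        t0 = lake_cycles[0].t_sunrise.ceil("min")
        t1 = lake_cycles[-1].t_next_sunrise.floor("min")
        minutes = pd.date_range(t0, t1, freq="1min")
        m = _day_modulation(minutes, lake_cycles, scenario.r_true, scenario.ramp_minutes)
        hour_idx = ((minutes - minutes[0]) // _HOUR).astype(int)
        n_hours = int(hour_idx.max()) + 1
        span_days = (t1 - t0) / pd.Timedelta(days=1)

        for ci, spec in enumerate(lake.chambers):
            rng_noise = _chamber_rng(scenario, li, ci, 0)
            rng_ebul = _chamber_rng(scenario, li, ci, 1)
            if scenario.flux_noise_sigma > 0:
                z = _stationary_ar1(n_hours, scenario.ar1_phi, rng_noise)
                noise = np.exp(scenario.flux_noise_sigma * z)[hour_idx]
            else:
                noise = 1.0
            diffusive = scenario.base_flux * m * noise

            ebul = np.zeros(len(minutes))
            if scenario.ebullition_rate > 0:
                n_events = rng_ebul.poisson(scenario.ebullition_rate * span_days)
                if n_events:
                    offsets = rng_ebul.uniform(0, (t1 - t0) / _MINUTE, size=n_events)
                    sizes = rng_ebul.exponential(scenario.ebullition_mean_size, n_events)
                    idx = np.minimum(offsets.astype(int), len(minutes) - 1)
                    np.add.at(ebul, idx, sizes)

            frames.append(
                pd.DataFrame(
                    {
                        "lake_id": lake.lake_id,
                        "chamber_id": spec.chamber_id,
                        "timestamp": minutes,
                        "diffusive_flux": diffusive,
                        "ebullition_umol_m2": ebul,
                    }
                )
            )
    return TruthTable(pd.concat(frames, ignore_index=True))


def simulate_met(
    scenario: SimScenario, cycles: dict[str, list[DielCycle]]
) -> dict[str, pd.DataFrame]:
    """Hourly meteorology per lake.

    Wind: diel sinusoid peaking early afternoon plus AR(1) noise, floored at
    zero.  PAR: clear-sky half-sine over daylight times a per-day cloud
    factor, zero at night.  Pressure: slow random walk around 1013 hPa with
    optional frontal drop events.  Air temperature: diel sinusoid.  Water
    temperature: near-constant (tiny diel amplitude).  Also carries the
    background CH4 reference series used for sensor calibration.
    """
    p = scenario.met
    out: dict[str, pd.DataFrame] = {}
    for li, lake in enumerate(scenario.lakes):
        lake_cycles = cycles[lake.lake_id]
        t0 = lake_cycles[0].t_sunrise.floor("h") - _HOUR
        t1 = lake_cycles[-1].t_next_sunrise.ceil("h") + _HOUR
        hours = pd.date_range(t0, t1, freq="1h")
        n = len(hours)
        rng = np.random.default_rng([scenario.rng_seed, 3000 + li])
        local_hour = (hours.hour + hours.minute / 60.0 + lake.utc_offset) % 24

        wind_diel = p.wind_mean + p.wind_diel_amp * np.cos(
            2 * np.pi * (local_hour - p.wind_peak_local_hour) / 24.0
        )
        wind_noise = _stationary_ar1(n, p.wind_ar1_phi, rng) * p.wind_noise_sd
        wind = np.clip(wind_diel + wind_noise, 0.0, None)

        par = np.zeros(n)
        day_of = hours.normalize()
        uniq_days = day_of.unique()
        cloud = dict(
            zip(uniq_days, rng.uniform(*p.cloud_factor_range, size=len(uniq_days)))
        )
        t_arr = hours.values
        for c in lake_cycles:
            sr, ss = np.datetime64(c.t_sunrise), np.datetime64(c.t_sunset)
            in_day = (t_arr >= sr) & (t_arr <= ss)
            frac = (t_arr[in_day] - sr).astype("timedelta64[s]").astype(float) / (
                (ss - sr).astype("timedelta64[s]").astype(float)
            )
            cf = np.array([cloud[d] for d in day_of[in_day]])
            par[in_day] = p.par_peak * np.sin(np.pi * frac) * cf

        pressure = p.pressure_mean + np.cumsum(rng.normal(0, p.pressure_step_sd, n))
        pressure -= pressure.mean() - p.pressure_mean
        for start, slope, dur_h in p.frontal_events:
            start = pd.Timestamp(start)
            dt_h = (hours - start) / _HOUR
            ramp = np.clip(dt_h, 0.0, dur_h)
            pressure = pressure + slope * np.asarray(ramp)

        air_temp = p.air_temp_mean + p.air_temp_diel_amp * np.cos(
            2 * np.pi * (local_hour - p.air_temp_peak_local_hour) / 24.0
        )
        water_temp = p.water_temp_mean + p.water_temp_diel_amp * np.cos(
            2 * np.pi * (local_hour - p.air_temp_peak_local_hour) / 24.0
        )
        ambient = scenario.ambient_ch4 + scenario.ambient_sigma * _stationary_ar1(
            n, 0.9, rng
        )

        out[lake.lake_id] = pd.DataFrame(
            {
                "timestamp": hours,
                "air_temp_c": air_temp,
                "pressure_hpa": pressure,
                "wind10_ms": wind,
                "par_umol_m2_s": par,
                "water_temp_c": water_temp,
                "ambient_ch4_ppm": np.clip(ambient, 0.1, None),
            }
        )
    return out


def _hourly_to_minutes(met: pd.DataFrame, minutes: pd.DatetimeIndex, col: str) -> np.ndarray:
    s = met.set_index("timestamp")[col]
    return s.reindex(minutes, method="ffill").to_numpy(dtype=float)


def _chamber_schedule(
    spec: ChamberSpec, minutes: pd.DatetimeIndex
) -> tuple[np.ndarray, np.ndarray]:
    """(state closed?, closure_id) per minute for the chamber's duty cycle.

    Automated chambers alternate closed accumulation and open flushing;
    manual chambers are consecutive closed deployments (sampled only at the
    endpoints downstream).
    """
    n = len(minutes)
    closed_min = int(round(spec.closure_hours * 60))
    flush_min = int(round(spec.flush_minutes)) if spec.kind == "automated" else 0
    period = closed_min + flush_min
    offset = np.arange(n) % period
    closed = offset < closed_min
    closure_id = np.arange(n) // period
    return closed, closure_id


def render_sensor_records(
    truth: TruthTable,
    scenario: SimScenario,
    met: dict[str, pd.DataFrame],
    qc_log: dict | None = None,
) -> list[ClosureSeries]:
    """Render the chamber measurement process on top of the flux truth.

    Within each closure the headspace concentration integrates the slope
    F(t) * R * T / (P * V/A) [ppm h-1] from the ambient background at closure
    start; ebullition events appear as instantaneous concentration steps.
    During flushing the concentration is the ambient background.  The raw
    signal is the exact inverse of the scenario's calibration model plus
    white noise, so calibration is exercised end to end.  Manual chambers
    emit only the grab samples at the start and end of each deployment.
    """
    cal = scenario.true_calibration
    out: list[ClosureSeries] = []
    for li, lake in enumerate(scenario.lakes):
        lake_met = met[lake.lake_id]
        for ci, spec in enumerate(lake.chambers):
            df = truth.chamber_slice(spec.chamber_id)
            minutes = pd.DatetimeIndex(df["timestamp"])
            local_hour = (
                minutes.hour + minutes.minute / 60.0 + lake.utc_offset
            ) % 24

            air_t = _hourly_to_minutes(lake_met, minutes, "air_temp_c")
            press_pa = _hourly_to_minutes(lake_met, minutes, "pressure_hpa") * 100.0
            ambient = _hourly_to_minutes(lake_met, minutes, "ambient_ch4_ppm")
            temp_c = air_t + scenario.met.headspace_temp_offset
            rh = np.clip(
                75.0 - 15.0 * np.cos(2 * np.pi * (local_hour - 15.0) / 24.0), 30.0, 100.0
            )

            temp_k = temp_c + 273.15
            unit = R_GAS * temp_k / (press_pa * spec.v_over_a_m)  # ppm per umol m-2
            slope_ppm_h = df["diffusive_flux"].to_numpy() * unit
            step_ppm = df["ebullition_umol_m2"].to_numpy() * unit

            closed, closure_id = _chamber_schedule(spec, minutes)
            # per-minute increments: diffusive growth since previous sample
            # plus any ebullition step landing in this minute
            inc = np.zeros(len(minutes))
            inc[1:] = slope_ppm_h[:-1] / 60.0
            inc += step_ppm
            first_of_closure = np.ones(len(minutes), dtype=bool)
            first_of_closure[1:] = (closure_id[1:] != closure_id[:-1]) | ~closed[:-1]
            inc[first_of_closure] = 0.0

            grp = pd.Series(inc).groupby(closure_id).cumsum().to_numpy()
            start_amb = pd.Series(np.where(first_of_closure, ambient, np.nan)).ffill()
            ppm = np.where(closed, start_amb.to_numpy() + grp, ambient)

            rng = _chamber_rng(scenario, li, ci, 2)
            if spec.kind == "automated":
                raw_clean = (ppm - cal.beta0 - cal.beta2 * absolute_humidity(rh, temp_c)) / cal.beta1
                raw = raw_clean + rng.normal(0, scenario.sensor_noise_sd, len(ppm))
                rec = pd.DataFrame(
                    {
                        "timestamp": minutes,
                        "raw_signal": raw,
                        "ch4_ppm_true": ppm,
                        "rh_pct": rh,
                        "temp_c": temp_c,
                        "state": np.where(closed, "closed", "open"),
                        "closure_id": closure_id,
                    }
                )
                # drop closures that ended up with < 2 samples
                counts = rec[rec["state"] == "closed"].groupby("closure_id").size()
                short = counts[counts < 2].index
                if len(short) and qc_log is not None:
                    qc_log["closure_dropped_lt2_samples"] = qc_log.get(
                        "closure_dropped_lt2_samples", 0
                    ) + len(short)
                rec = rec[~((rec["state"] == "closed") & rec["closure_id"].isin(short))]
            else:
                # manual: grab samples at deployment start and end only
                idx = np.zeros(len(minutes), dtype=bool)
                last_of_closure = np.ones(len(minutes), dtype=bool)
                last_of_closure[:-1] = closure_id[1:] != closure_id[:-1]
                idx |= first_of_closure & closed
                idx |= last_of_closure & closed
                samp = np.flatnonzero(idx)
                meas = ppm[samp]
                if scenario.manual_noise_ppm > 0:
                    meas = meas + rng.normal(0, scenario.manual_noise_ppm, len(samp))
                rec = pd.DataFrame(
                    {
                        "timestamp": minutes[samp],
                        "ch4_ppm": meas,
                        "ch4_ppm_true": ppm[samp],
                        "rh_pct": rh[samp],
                        "temp_c": temp_c[samp],
                        "state": "closed",
                        "closure_id": closure_id[samp],
                    }
                )
                counts = rec.groupby("closure_id").size()
                short = counts[counts < 2].index
                if len(short) and qc_log is not None:
                    qc_log["closure_dropped_lt2_samples"] = qc_log.get(
                        "closure_dropped_lt2_samples", 0
                    ) + len(short)
                rec = rec[~rec["closure_id"].isin(short)]

            out.append(
                ClosureSeries(
                    chamber_id=spec.chamber_id,
                    records=rec.reset_index(drop=True),
                    geometry=spec,
                    lake_id=lake.lake_id,
                )
            )
    return out


def default_scenario(
    rng_seed: int = 42,
    n_days: int = 30,
    r_true: float = 2.5,
    flux_noise_sigma: float = 0.3,
    **overrides,
) -> SimScenario:
    """Two-lake, five-chamber scenario used by the examples and acceptance runs."""
    lakes = (
        LakeConfig(
            lake_id="SIM-N",
            latitude=58.4,
            longitude=14.6,
            utc_offset=1.0,
            season_label="stratified",
            chambers=(
                ChamberSpec("SIM-N-C1", depth_m=0.9, volume_m3=0.03, area_m2=0.1,
                            kind="automated", closure_hours=1.0),
                ChamberSpec("SIM-N-C2", depth_m=1.8, volume_m3=0.03, area_m2=0.1,
                            kind="automated", closure_hours=2.0),
                ChamberSpec("SIM-N-C3", depth_m=3.5, volume_m3=0.03, area_m2=0.1,
                            kind="automated", closure_hours=0.5),
            ),
        ),
        LakeConfig(
            lake_id="SIM-S",
            latitude=57.3,
            longitude=12.2,
            utc_offset=1.0,
            season_label="mixing",
            chambers=(
                ChamberSpec("SIM-S-C1", depth_m=0.4, volume_m3=0.025, area_m2=0.09,
                            kind="automated", closure_hours=1.5),
                ChamberSpec("SIM-S-C2", depth_m=1.2, volume_m3=0.025, area_m2=0.09,
                            kind="automated", closure_hours=3.0),
            ),
        ),
    )
    return SimScenario(
        lakes=lakes,
        n_days=n_days,
        r_true=r_true,
        flux_noise_sigma=flux_noise_sigma,
        rng_seed=rng_seed,
        **overrides,
    )
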