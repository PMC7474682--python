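"""Floating-chamber CH4 flux computation.

Converts chamber headspace concentration records into fluxes in
umol m-2 h-1 via the ideal gas law, with a three-parameter linear sensor
calibration (signal + absolute humidity) and quality screening.

Endpoint differencing (mean of first k vs last k records) is used rather
than a regression slope so that episodic ebullition steps inside a closure
are retained in the flux estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol-1 K-1
_MW_WATER = 18.015  # g mol-1

REQUIRED_RECORD_COLUMNS = ("timestamp", "rh_pct", "temp_c", "state")
VALID_STATES = frozenset({"open", "closed"})


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and sampling mode of one floating chamber."""

    chamber_id: str
    depth_m: float
    volume_m3: float
    area_m2: float
    kind: str = "automated"  # "automated" | "manual"
    closure_hours: float = 1.0
    flush_minutes: float = 20.0

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0 or self.area_m2 <= 0:
            raise ValueError(f"{self.chamber_id}: volume and area must be positive")
        if self.depth_m <= 0:
            raise ValueError(f"{self.chamber_id}: depth must be positive")
        if self.closure_hours <= 0:
            raise ValueError(f"{self.chamber_id}: closure_hours must be positive")
        if self.kind not in ("automated", "manual"):
            raise ValueError(f"{self.chamber_id}: kind must be automated|manual")

    @property
    def v_over_a_m(self) -> float:
        """Effective headspace height V/A in metres."""
        return self.volume_m3 / self.area_m2


@dataclass
class ClosureSeries:
    """One chamber deployment's timestamped sensor records."""

    chamber_id: str
    records: pd.DataFrame
    geometry: ChamberSpec
    lake_id: str = ""

    def __post_init__(self) -> None:
        df = self.records
        for col in REQUIRED_RECORD_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"{self.chamber_id}: records missing column {col!r}")
        ts = pd.to_datetime(df["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"{self.chamber_id}: timestamps must strictly increase")
        bad = set(df["state"].unique()) - VALID_STATES
        if bad:
            raise ValueError(f"{self.chamber_id}: invalid states {sorted(bad)}")
        self.records = df.assign(timestamp=ts).reset_index(drop=True)


@dataclass(frozen=True)
class CalibrationModel:
    """ppm = beta0 + beta1 * raw_signal + beta2 * absolute_humidity."""

    beta0: float
    beta1: float
    beta2: float
    n: int = 0
    rmse_ppm: float = float("nan")
    ok: bool = True
    note: str = ""

    def predict_ppm(self, raw, abs_humidity) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(raw) + self.beta2 * np.asarray(
            abs_humidity
        )


@dataclass(frozen=True)
class FluxRecord:
    """One chamber flux estimate in umol m-2 h-1."""

    chamber_id: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    duration_h: float
    flux: float
    method: str  # "afc_endpoints" | "manual_two_point"
    lake_id: str = ""
    qc: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if not math.isfinite(self.flux):
            raise ValueError("flux must be finite")


def absolute_humidity(rh_pct, temp_c) -> np.ndarray:
    """Absolute humidity [g m-3] from RH [%] and temperature [degC].

    Saturation vapour pressure from the Magnus formula; vapour density via
    the ideal gas law.
    """
    rh = np.asarray(rh_pct, dtype=float)
    t = np.asarray(temp_c, dtype=float)
    e_sat_pa = 611.2 * np.exp(17.62 * t / (243.12 + t))
    e_pa = rh / 100.0 * e_sat_pa
    return e_pa * _MW_WATER / (R_GAS * (t + 273.15))


def flux_from_slope(
    slope_ppm_per_h: float, v_over_a_m: float, temp_k: float, pressure_pa: float
) -> float:
    """Ideal-gas conversion of a headspace slope to a flux [umol m-2 h-1].

    ppm is treated as umol CH4 per mol of (dry) air; the chamber holds
    P*V/(R*T) mol of air per m2 of water surface per (V/A) metres.
    """
    mol_per_m2 = pressure_pa * v_over_a_m / (R_GAS * temp_k)
    return slope_ppm_per_h * 1e-6 * mol_per_m2 * 1e6


def fit_calibration(
    series: ClosureSeries,
    ambient_ppm,
    wind: pd.Series,
    wind_threshold: float = 2.0,
    min_records: int = 10,
) -> CalibrationModel:
    """Fit the 3-parameter sensor calibration on well-mixed open-state records.

    Open-state (flushing) records during hours with wind speed above
    ``wind_threshold`` see background air, whose CH4 level is the reference.

    Parameters
    ----------
    ambient_ppm
        Background CH4: a scalar, or a timestamp-indexed Series (e.g. from a
        reference monitoring station) matched to record hours.  Note a strictly
        constant reference makes the design collinear (raw is then an affine
        function of humidity), so a time-varying reference is recommended.
    wind
        Hourly wind speed [m s-1] indexed by timestamp.
    """
    df = series.records
    if "raw_signal" not in df.columns:
        return CalibrationModel(0, 1, 0, 0, ok=False, note="no raw_signal column")
    open_recs = df[df["state"] == "open"].dropna(subset=["raw_signal", "rh_pct", "temp_c"])
    hours = open_recs["timestamp"].dt.floor("h")
    w = wind.reindex(hours).to_numpy()
    open_recs = open_recs[w > wind_threshold]
    if len(open_recs) < min_records:
        return CalibrationModel(
            0, 1, 0, len(open_recs), ok=False,
            note=f"calibration failure: {len(open_recs)} qualifying records "
            f"(need {min_records})",
        )

    ah = absolute_humidity(open_recs["rh_pct"], open_recs["temp_c"])
    raw = open_recs["raw_signal"].to_numpy(dtype=float)
    if np.isscalar(ambient_ppm):
        y = np.full(len(open_recs), float(ambient_ppm))
    else:
        hrs = open_recs["timestamp"].dt.floor("h")
        y = pd.Series(ambient_ppm).reindex(hrs).to_numpy(dtype=float)
        keep = np.isfinite(y)
        y, raw, ah = y[keep], raw[keep], ah[keep]
        if len(y) < min_records:
            return CalibrationModel(
                0, 1, 0, int(len(y)), ok=False,
                note="calibration failure: too few records with reference ppm",
            )

    X = np.column_stack([np.ones_like(raw), raw, ah])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rmse = float(np.sqrt(np.mean(resid**2)))
    ok, note = True, ""
    if rank < 3:
        ok, note = False, "calibration failure: collinear design (rank-deficient)"
    elif beta[1] <= 0:
        ok, note = False, "non-physical calibration: beta1 <= 0"
    return CalibrationModel(
        float(beta[0]), float(beta[1]), float(beta[2]), int(len(y)), rmse, ok, note
    )


def impute_rh_temp(
    all_series: list[ClosureSeries],
    tolerance: pd.Timedelta = pd.Timedelta(minutes=15),
) -> list[ClosureSeries]:
    """Fill missing RH/temperature from the closest chamber, nearest in time.

    "Closest" uses depth proximity within the same lake as the spatial proxy
    (chamber coordinates are not part of the record schema); the donor record
    must lie within ``tolerance`` of the gap.  Imputed records get
    ``imputed_rh_temp=True``; records no donor can fill are dropped with the
    count recorded in ``qc_excluded`` on the returned series.
    """
    out: list[ClosureSeries] = []
    for s in all_series:
        df = s.records.copy()
        missing = df["rh_pct"].isna() | df["temp_c"].isna()
        df["imputed_rh_temp"] = False
        if not missing.any():
            out.append(ClosureSeries(s.chamber_id, df, s.geometry, s.lake_id))
            continue
        donors = sorted(
            (d for d in all_series if d is not s and d.lake_id == s.lake_id),
            key=lambda d: abs(d.geometry.depth_m - s.geometry.depth_m),
        )
        for donor in donors:
            if not missing.any():
                break
            dd = donor.records.dropna(subset=["rh_pct", "temp_c"])
            if dd.empty:
                continue
            target = df.loc[missing, ["timestamp"]].reset_index()
            filled = pd.merge_asof(
                target.sort_values("timestamp"),
                dd[["timestamp", "rh_pct", "temp_c"]].sort_values("timestamp"),
                on="timestamp",
                direction="nearest",
                tolerance=tolerance,
            ).set_index("index")
            df.loc[filled.index, "rh_pct"] = filled["rh_pct"]
            df.loc[filled.index, "temp_c"] = filled["temp_c"]
            df.loc[filled.index, "imputed_rh_temp"] = True
            missing = df["rh_pct"].isna() | df["temp_c"].isna()
        n_dropped = int(missing.sum())
        df = df[~missing].reset_index(drop=True)
        new = ClosureSeries(s.chamber_id, df, s.geometry, s.lake_id)
        new.qc_excluded = n_dropped  # type: ignore[attr-defined]
        out.append(new)
    return out


def _closure_groups(df: pd.DataFrame) -> Iterable[pd.DataFrame]:
    """Yield runs of consecutive closed-state records (one per closure)."""
    closed = df["state"] == "closed"
    if "closure_id" in df.columns:
        for _, grp in df[closed].groupby("closure_id", sort=True):
            yield grp
        return
    run_id = (closed != closed.shift()).cumsum()
    for _, grp in df[closed].groupby(run_id[closed], sort=True):
        yield grp


def _mean_pressure_pa(pressure_hpa: pd.Series, t0: pd.Timestamp, t1: pd.Timestamp) -> float:
    sel = pressure_hpa[(pressure_hpa.index >= t0.floor("h")) & (pressure_hpa.index <= t1)]
    if sel.empty:
        raise ValueError(f"no pressure data covering {t0}..{t1}")
    return float(sel.mean()) * 100.0


def compute_afc_flux(
    series: ClosureSeries,
    cal: CalibrationModel | None,
    pressure_hpa: pd.Series,
    k: int = 3,
    min_records: int = 5,
    min_duration_h: float = 0.2,
    qc_log: dict | None = None,
) -> list[FluxRecord]:
    """Per-closure endpoint-difference fluxes for an automated chamber.

    dC = mean(last k ppm) - mean(first k ppm); dt spans the two window
    centres.  T and P are averaged over the closure.  Closures failing the
    quality screen (record count, duration, failed calibration) produce no
    record; exclusion reasons are tallied in ``qc_log`` when given.
    """
    df = series.records
    if "ch4_ppm" in df.columns:
        ppm_all = df["ch4_ppm"].to_numpy(dtype=float)
    else:
        if cal is None or not cal.ok:
            if qc_log is not None:
                qc_log["calibration_failed"] = qc_log.get("calibration_failed", 0) + 1
            return []
        ah = absolute_humidity(df["rh_pct"], df["temp_c"])
        ppm_all = cal.predict_ppm(df["raw_signal"], ah)

    records: list[FluxRecord] = []

    def _log(reason: str) -> None:
        if qc_log is not None:
            qc_log[reason] = qc_log.get(reason, 0) + 1

    for grp in _closure_groups(df):
        if len(grp) < max(min_records, 2 * k):
            _log("closure_too_few_records")
            continue
        ts = grp["timestamp"]
        t_start, t_end = ts.iloc[0], ts.iloc[-1]
        duration_h = (t_end - t_start) / pd.Timedelta(hours=1)
        if duration_h < min_duration_h:
            _log("closure_too_short")
            continue
        ppm = ppm_all[grp.index]
        d_conc = float(np.mean(ppm[-k:]) - np.mean(ppm[:k]))
        t_first = ts.iloc[:k].mean()
        t_last = ts.iloc[-k:].mean()
        dt_h = (t_last - t_first) / pd.Timedelta(hours=1)
        if dt_h <= 0:
            _log("closure_zero_span")
            continue
        temp_k = float(grp["temp_c"].mean()) + 273.15
        p_pa = _mean_pressure_pa(pressure_hpa, t_start, t_end)
        flux = flux_from_slope(d_conc / dt_h, series.geometry.v_over_a_m, temp_k, p_pa)
        qc = set()
        if "imputed_rh_temp" in grp.columns and grp["imputed_rh_temp"].any():
            qc.add("imputed_rh_temp")
        records.append(
            FluxRecord(
                chamber_id=series.chamber_id,
                t_start=t_start,
                t_end=t_end,
                duration_h=duration_h,
                flux=flux,
                method="afc_endpoints",
                lake_id=series.lake_id,
                qc=frozenset(qc),
            )
        )
    return records


def compute_manual_flux(
    samples: Sequence[tuple[pd.Timestamp, float]],
    geometry: ChamberSpec,
    temp_c: float,
    pressure_hpa: float,
    chamber_id: str | None = None,
    lake_id: str = "",
    qc_log: dict | None = None,
) -> FluxRecord | None:
    """Two-point (first/last grab sample) flux for a manual chamber."""
    if len(samples) < 2:
        if qc_log is not None:
            qc_log["manual_single_sample"] = qc_log.get("manual_single_sample", 0) + 1
        return None
    samples = sorted(samples, key=lambda s: pd.Timestamp(s[0]))
    (t0, c0), (t1, c1) = samples[0], samples[-1]
    t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
    dt_h = (t1 - t0) / pd.Timedelta(hours=1)
    if dt_h <= 0:
        if qc_log is not None:
            qc_log["manual_zero_span"] = qc_log.get("manual_zero_span", 0) + 1
        return None
    flux = flux_from_slope(
        (c1 - c0) / dt_h, geometry.v_over_a_m, temp_c + 273.15, pressure_hpa * 100.0
    )
    return FluxRecord(
        chamber_id=chamber_id or geometry.chamber_id,
        t_start=t0,
        t_end=t1,
        duration_h=dt_h,
        flux=flux,
        method="manual_two_point",
        lake_id=lake_id,
    )


def manual_series_fluxes(
    series: ClosureSeries,
    pressure_hpa: pd.Series,
    qc_log: dict | None = None,
) -> list[FluxRecord]:
    """Fluxes for a rendered manual-chamber series (grab samples per closure)."""
    out: list[FluxRecord] = []
    for grp in _closure_groups(series.records):
        if len(grp) < 2:
            if qc_log is not None:
                qc_log["manual_single_sample"] = qc_log.get("manual_single_sample", 0) + 1
            continue
        samples = list(zip(grp["timestamp"], grp["ch4_ppm"]))
        t0, t1 = grp["timestamp"].iloc[0], grp["timestamp"].iloc[-1]
        rec = compute_manual_flux(
            samples,
            series.geometry,
            temp_c=float(grp["temp_c"].mean()),
            pressure_hpa=_mean_pressure_pa(pressure_hpa, t0, t1) / 100.0,
            chamber_id=series.chamber_id,
            lake_id=series.lake_id,
            qc_log=qc_log,
        )
        if rec is not None:
            out.append(rec)
    return out


def fluxes_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    """Tabular view of flux records for CSV export and statistics."""
    records = list(records)
    return pd.DataFrame(
        {
            "lake_id": [r.lake_id for r in records],
            "chamber_id": [r.chamber_id for r in records],
            "t_start": [r.t_start for r in records],
            "t_end": [r.t_end for r in records],
            "duration_h": [r.duration_h for r in records],
            "flux_umol_m2_h": [r.flux for r in records],
            "method": [r.method for r in records],
            "qc": ["|".join(sorted(r.qc)) for r in records],
        }
    )
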