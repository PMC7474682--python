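"""Candidate-driver diagnostics for diel flux patterns.

Per-cycle day:night ratios of wind, water temperature, delta-T and PAR;
maximum pressure drop from moving 4-h regression windows; the
similar-wind/pressure-drop subset with its FL_R rank correlation; wind-flux
concordance fractions; and the FL_R vs light-period relation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .solar import DielCycle

_HOUR = pd.Timedelta(hours=1)


def _window_weighted_mean(
    hourly: pd.Series, t0: pd.Timestamp, t1: pd.Timestamp
) -> tuple[float, float]:
    """Duration-weighted mean of an hourly (step-held) series over [t0, t1].

    Returns (mean, coverage fraction); NaN hours reduce coverage.
    """
    total_h = (t1 - t0) / _HOUR
    vals, ws = [], []
    edge = t0.floor("h")
    while edge < t1:
        nxt = edge + _HOUR
        w = (min(t1, nxt) - max(t0, edge)) / _HOUR
        if w > 0 and edge in hourly.index:
            v = hourly.loc[edge]
            if np.isfinite(v):
                vals.append(v)
                ws.append(w)
        edge = nxt
    if not ws:
        return float("nan"), 0.0
    return float(np.average(vals, weights=ws)), float(sum(ws) / total_h)


def max_pressure_drop(pressure: pd.Series, window_h: int = 4) -> float | None:
    """Most negative OLS slope [hPa h-1] over moving ``window_h``-point runs.

    ``pressure`` is an hourly series within one day or night window.  Runs
    step by one hour; returns None when fewer than ``window_h`` points are
    available or no window has a negative slope.
    """
    p = pressure.dropna()
    if len(p) < window_h:
        return None
    t_h = (p.index - p.index[0]) / _HOUR
    x = np.asarray(t_h, dtype=float)
    y = p.to_numpy(dtype=float)
    slopes = []
    for i in range(len(p) - window_h + 1):
        xi, yi = x[i : i + window_h], y[i : i + window_h]
        # consecutive hourly run only: skip windows spanning data gaps
        if xi[-1] - xi[0] != window_h - 1:
            continue
        slopes.append(float(np.polyfit(xi, yi, 1)[0]))
    neg = [s for s in slopes if s < 0]
    return min(neg) if neg else None


def driver_day_night_ratios(
    met: pd.DataFrame,
    cycles: list[DielCycle],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-cycle duration-weighted day/night driver means and their ratios.

    ``met`` is the hourly lake table (air_temp_c, pressure_hpa, wind10_ms,
    par_umol_m2_s, water_temp_c).  delta-T is water minus air temperature
    (positive when the water is warmer).  PAR has no night ratio (night mean
    is ~0); the day mean is reported instead.  Cycles with less than
    ``min_coverage`` of either window covered are flagged incomplete.
    """
    m = met.set_index("timestamp")
    wind = m["wind10_ms"]
    wtemp = m["water_temp_c"]
    par = m["par_umol_m2_s"]
    dT = m["water_temp_c"] - m["air_temp_c"]
    pres = m["pressure_hpa"]

    rows = []
    for c in cycles:
        day_win = (c.t_sunrise, c.t_sunset)
        night_win = (c.t_sunset, c.t_next_sunrise)
        wind_d, cov_d = _window_weighted_mean(wind, *day_win)
        wind_n, cov_n = _window_weighted_mean(wind, *night_win)
        wt_d, _ = _window_weighted_mean(wtemp, *day_win)
        wt_n, _ = _window_weighted_mean(wtemp, *night_win)
        dt_d, _ = _window_weighted_mean(dT, *day_win)
        dt_n, _ = _window_weighted_mean(dT, *night_win)
        par_d, _ = _window_weighted_mean(par, *day_win)

        drop_d = max_pressure_drop(pres[day_win[0] : day_win[1]])
        drop_n = max_pressure_drop(pres[night_win[0] : night_win[1]])
        drop_ratio = (
            drop_d / drop_n if (drop_d is not None and drop_n is not None) else np.nan
        )
        rows.append(
            {
                "lake_id": c.lake_id,
                "cycle_index": c.cycle_index,
                "wind_day": wind_d,
                "wind_night": wind_n,
                "wind_ratio": wind_d / wind_n if wind_n > 0 else np.nan,
                "watertemp_ratio": wt_d / wt_n if wt_n > 0 else np.nan,
                "deltaT_day": dt_d,
                "deltaT_night": dt_n,
                "par_day_mean": par_d,
                "pressure_drop_day": np.nan if drop_d is None else drop_d,
                "pressure_drop_night": np.nan if drop_n is None else drop_n,
                "pressure_drop_ratio": drop_ratio,
                "incomplete": bool(min(cov_d, cov_n) < min_coverage),
            }
        )
    return pd.DataFrame(rows)


def pressure_ratio_subset(
    summaries: pd.DataFrame,
    flr: pd.DataFrame,
    wind_band: tuple[float, float] = (0.7, 1.3),
) -> dict:
    """Cycles with pressure drops in both periods and similar day/night wind.

    Keeps cycles whose day and night windows both show a negative pressure
    slope and whose wind ratio lies in ``wind_band``, then reports the
    Spearman correlation of the day:night pressure-drop ratio with FL_R.
    """
    sel = summaries[
        summaries["pressure_drop_day"].notna()
        & summaries["pressure_drop_night"].notna()
        & (summaries["pressure_drop_day"] < 0)
        & (summaries["pressure_drop_night"] < 0)
        & summaries["wind_ratio"].between(*wind_band)
    ]
    merged = sel.merge(
        flr.dropna(subset=["FL_R"]), on=["lake_id", "cycle_index"], how="inner"
    )
    out = {
        "n_cycles": int(len(sel)),
        "n_pairs": int(len(merged)),
        "subset": merged,
        "spearman_rho": float("nan"),
        "p_value": float("nan"),
    }
    if len(merged) >= 3 and merged["pressure_drop_ratio"].nunique() > 1:
        rho, p = sps.spearmanr(merged["pressure_drop_ratio"], merged["FL_R"])
        out["spearman_rho"], out["p_value"] = float(rho), float(p)
    return out


def wind_flux_concordance(flr: pd.DataFrame, summaries: pd.DataFrame) -> dict:
    """Concordance between daytime-elevated wind and daytime-elevated flux.

    Reports: among FL_R > 1 records, the fraction with day:night wind ratio
    above 1; and among wind-ratio > 1 records, the fraction whose FL_R did
    *not* exceed 1.  Counts accompany each fraction.
    """
    merged = flr.dropna(subset=["FL_R"]).merge(
        summaries[["lake_id", "cycle_index", "wind_ratio"]],
        on=["lake_id", "cycle_index"],
        how="inner",
    ).dropna(subset=["wind_ratio"])
    flr_gt1 = merged[merged["FL_R"] > 1]
    wind_gt1 = merged[merged["wind_ratio"] > 1]
    return {
        "n_pairs": int(len(merged)),
        "n_flr_gt1": int(len(flr_gt1)),
        "frac_flr_gt1_with_wind_gt1": (
            float((flr_gt1["wind_ratio"] > 1).mean()) if len(flr_gt1) else float("nan")
        ),
        "n_wind_gt1": int(len(wind_gt1)),
        "frac_wind_gt1_without_flr_gt1": (
            float((wind_gt1["FL_R"] <= 1).mean()) if len(wind_gt1) else float("nan")
        ),
    }


def flr_vs_light(flr: pd.DataFrame, min_n: int = 5) -> dict:
    """(light_period_h, FL_R) pairs with their Spearman rank correlation."""
    pairs = flr.dropna(subset=["FL_R"])[
        ["lake_id", "unit_id", "cycle_index", "light_period_h", "FL_R"]
    ].reset_index(drop=True)
    out = {
        "pairs": pairs,
        "n": int(len(pairs)),
        "spearman_rho": float("nan"),
        "p_value": float("nan"),
    }
    if len(pairs) < min_n:
        return out
    if pairs["FL_R"].nunique() == 1 or pairs["light_period_h"].nunique() == 1:
        # zero variance in one margin: no monotone association by convention
        out["spearman_rho"], out["p_value"] = 0.0, 1.0
        return out
    rho, p = sps.spearmanr(pairs["light_period_h"], pairs["FL_R"])
    out["spearman_rho"], out["p_value"] = float(rho), float(p)
    return out
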