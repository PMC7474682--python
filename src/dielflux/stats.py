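"""Diel flux statistics.

Hourly time-weighted geometric flux profiles over the clock day, per-cycle
day:night flux ratios (FL_R) with duration-weighted arithmetic day/night
means, depth binning, and the nonparametric day-vs-night comparisons.

Conventions: hourly profiles use the weighted *geometric* mean (robust to
episodic ebullition spikes) on positive fluxes only, while FL_R uses
duration-weighted *arithmetic* means; day/night for FL_R is sunrise/sunset
based, whereas the clock-window rank test uses local clock hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .solar import DielCycle, split_day_night

_HOUR = pd.Timedelta(hours=1)

DEPTH_BIN_EDGES = (0.5, 1.0, 1.5)
DEPTH_BIN_LABELS = ("<0.5", "0.5-1", "1-1.5", ">1.5")


def weighted_geometric_mean(values, weights=None) -> float:
    """exp( sum(w*ln x) / sum(w) ) for positive values and weights.

    Raises on non-positive values: callers must filter (and count) them.
    Returns NaN for empty input.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return float("nan")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("weighted geometric mean requires positive finite values")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    return float(np.exp(np.average(np.log(x), weights=w)))


def _hour_overlaps(
    t_start: pd.Timestamp, t_end: pd.Timestamp, utc_offset: float
) -> list[tuple[int, float]]:
    """(hour_of_day, overlap hours) of a local-clock interval with hour bins."""
    shift = pd.Timedelta(hours=utc_offset)
    s, e = t_start + shift, t_end + shift
    out = []
    edge = s.floor("h")
    while edge < e:
        nxt = edge + _HOUR
        lo, hi = max(s, edge), min(e, nxt)
        w = (hi - lo) / _HOUR
        if w > 0:
            out.append((int(edge.hour), w))
        edge = nxt
    return out


def hourly_profile(
    fluxes: pd.DataFrame,
    utc_offset: float,
    lake_id: str | None = None,
    season_label: str = "",
) -> pd.DataFrame:
    """Per clock-hour weighted geometric mean flux over the whole record.

    Each flux interval contributes to every local clock hour it overlaps,
    weighted by the overlap duration.  Non-positive fluxes are excluded from
    the geometric mean; their count is carried in ``n_excluded_nonpositive``.

    Returns a frame with one row per hour that has data (missing hours are
    absent, not zero).
    """
    df = fluxes if lake_id is None else fluxes[fluxes["lake_id"] == lake_id]
    n_excluded = int((df["flux_umol_m2_h"] <= 0).sum())
    df = df[df["flux_umol_m2_h"] > 0]

    per_hour: dict[int, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        for hour, w in _hour_overlaps(row.t_start, row.t_end, utc_offset):
            per_hour.setdefault(hour, []).append((row.flux_umol_m2_h, w))

    rows = []
    for hour in sorted(per_hour):
        vals, ws = zip(*per_hour[hour])
        rows.append(
            {
                "lake_id": lake_id if lake_id is not None else "",
                "season_label": season_label,
                "hour_of_day": hour,
                "gw_mean_flux": weighted_geometric_mean(vals, ws),
                "n_obs": len(vals),
                "total_weight_h": float(sum(ws)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "lake_id", "season_label", "hour_of_day",
            "gw_mean_flux", "n_obs", "total_weight_h",
        ],
    )
    out.attrs["n_excluded_nonpositive"] = n_excluded
    return out


def bin_by_depth(
    chambers: Sequence, edges: Sequence[float] = DEPTH_BIN_EDGES
) -> dict[str, str]:
    """Map chamber_id -> depth-bin label ([edge, next) convention, so a
    chamber at exactly 0.5 m falls in the "0.5-1" bin)."""
    labels = DEPTH_BIN_LABELS if tuple(edges) == DEPTH_BIN_EDGES else None
    if labels is None:
        labels = [f"<{edges[0]}"] + [
            f"{a}-{b}" for a, b in zip(edges, edges[1:])
        ] + [f">{edges[-1]}"]
    mapping: dict[str, str] = {}
    for ch in chambers:
        depth = getattr(ch, "depth_m", None)
        if depth is None or (isinstance(depth, float) and math.isnan(depth)):
            continue  # unbinned; caller sees the missing key as the flag
        idx = int(np.searchsorted(np.asarray(edges, dtype=float), depth, side="right"))
        mapping[ch.chamber_id] = labels[idx]
    return mapping


def compute_flr(
    fluxes: pd.DataFrame,
    cycles: Sequence[DielCycle],
    unit_of: Mapping[str, str] | None = None,
    min_hours: float = 1.0,
) -> pd.DataFrame:
    """Per-unit, per-cycle day:night flux ratios.

    F_day is the duration-weighted arithmetic mean of fluxes over the
    sunrise..sunset window (each record weighted by its overlap with the
    window), F_night over sunset..next sunrise; FL_R = F_day / F_night.
    Units default to individual chambers; pass ``unit_of`` to pool chambers
    (e.g. by depth bin).  Records with F_night <= 0 keep their day/night
    means but an undefined FL_R (NaN, flagged); units with under
    ``min_hours`` of flux-time in either window are skipped.
    """
    if unit_of is None:
        unit_of = {c: c for c in fluxes["chamber_id"].unique()}
    df = fluxes[fluxes["chamber_id"].isin(unit_of)].copy()
    df["unit_id"] = df["chamber_id"].map(unit_of)

    rows = []
    for cycle in cycles:
        in_cycle = df[
            (df["lake_id"] == cycle.lake_id)
            & (df["t_end"] > cycle.t_sunrise)
            & (df["t_start"] < cycle.t_next_sunrise)
        ]
        for unit, grp in in_cycle.groupby("unit_id"):
            day_w, day_fw, night_w, night_fw = 0.0, 0.0, 0.0, 0.0
            for row in grp.itertuples(index=False):
                d, n = split_day_night(row.t_start, row.t_end, cycle)
                day_w += d
                day_fw += d * row.flux_umol_m2_h
                night_w += n
                night_fw += n * row.flux_umol_m2_h
            if day_w < min_hours or night_w < min_hours:
                continue
            f_day = day_fw / day_w
            f_night = night_fw / night_w
            flag = ""
            if f_night <= 0:
                flr = float("nan")
                flag = "undefined_flr_nonpositive_night"
            else:
                flr = f_day / f_night
            rows.append(
                {
                    "lake_id": cycle.lake_id,
                    "unit_id": unit,
                    "cycle_index": cycle.cycle_index,
                    "F_day": f_day,
                    "F_night": f_night,
                    "FL_R": flr,
                    "day_hours": day_w,
                    "night_hours": night_w,
                    "light_period_h": cycle.light_period_h,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lake_id", "unit_id", "cycle_index", "F_day", "F_night", "FL_R",
            "day_hours", "night_hours", "light_period_h", "flag",
        ],
    )


def flr_summary_by_unit(flr: pd.DataFrame) -> pd.DataFrame:
    """Unweighted arithmetic mean FL_R per unit (one point per unit)."""
    ok = flr.dropna(subset=["FL_R"])
    return (
        ok.groupby(["lake_id", "unit_id"], as_index=False)
        .agg(mean_flr=("FL_R", "mean"), n_cycles=("FL_R", "size"))
    )


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n_day: int
    n_night: int
    method: str
    flag: str = ""

    @property
    def ok(self) -> bool:
        return not self.flag


def wilcoxon_day_night(
    fluxes: pd.DataFrame,
    utc_offset: float,
    day_window: tuple[float, float] = (10.0, 16.0),
    night_window: tuple[float, float] = (0.0, 4.0),
    exact_max_n: int = 25,
) -> RankTestResult:
    """One-sided (day > night) rank-sum test on clock-window flux samples.

    Samples are flux records whose interval midpoints fall in the local
    clock windows.  Exact null distribution for combined n <= ``exact_max_n``,
    normal approximation with continuity correction otherwise.
    """
    mid = fluxes["t_start"] + (fluxes["t_end"] - fluxes["t_start"]) / 2
    local = (mid.dt.hour + mid.dt.minute / 60.0 + utc_offset) % 24
    day = fluxes.loc[(local >= day_window[0]) & (local < day_window[1]), "flux_umol_m2_h"]
    night = fluxes.loc[
        (local >= night_window[0]) & (local < night_window[1]), "flux_umol_m2_h"
    ]
    if day.empty or night.empty:
        return RankTestResult(float("nan"), float("nan"), len(day), len(night),
                              "none", flag="empty_window")
    method = "exact" if len(day) + len(night) <= exact_max_n else "asymptotic"
    res = sps.mannwhitneyu(day, night, alternative="greater", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), len(day),
                          len(night), method)


def flr_exceedance_test(
    flr_values,
    null_value: float = 1.0,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
    min_n: int = 4,
) -> dict:
    """One-sample signed-rank test of FL_R > ``null_value`` plus exceedance.

    Zero differences are dropped by default (Wilcoxon's treatment;
    ``zero_method='pratt'`` keeps them in the ranking).  The exact null is
    used for n <= ``exact_max_n``.  With fewer than ``min_n`` non-zero
    differences the test is skipped but the exceedance fraction is still
    reported.
    """
    x = np.asarray(pd.Series(flr_values).dropna(), dtype=float)
    out = {
        "n": int(x.size),
        "fraction_gt": float(np.mean(x > null_value)) if x.size else float("nan"),
        "statistic": float("nan"),
        "p_value": float("nan"),
        "flag": "",
    }
    d = x - null_value
    d_nz = d[d != 0]
    if d_nz.size < min_n:
        out["flag"] = "too_few_nonzero_differences"
        return out
    has_ties = len(np.unique(np.abs(d_nz))) < d_nz.size
    if d_nz.size <= exact_max_n and not has_ties:
        method = "exact"
    elif has_ties and d_nz.size <= 15:
        # exact sign-flip enumeration despite ties (2^n null evaluations)
        method = sps.PermutationMethod(n_resamples=2 ** d_nz.size)
    else:
        method = "approx"
    res = sps.wilcoxon(
        d, alternative="greater", zero_method=zero_method, method=method
    )
    method = "exact-permutation" if not isinstance(method, str) else method
    out["statistic"] = float(res.statistic)
    out["p_value"] = float(res.pvalue)
    out["method"] = method
    return out
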