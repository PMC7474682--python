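"""End-to-end pipeline: simulate -> calibrate -> flux -> cycles -> diel
statistics -> drivers -> upscaling, with file I/O, config handling and a run
manifest.

All stage outputs are plain CSV/JSON/YAML under the configured output
directory; a stage failure aborts with a stage-named error while earlier
outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chamber import (
    ChamberSpec,
    ClosureSeries,
    CalibrationModel,
    compute_afc_flux,
    fit_calibration,
    fluxes_frame,
    impute_rh_temp,
    manual_series_fluxes,
)
from .drivers import (
    driver_day_night_ratios,
    flr_vs_light,
    pressure_ratio_subset,
    wind_flux_concordance,
)
from .solar import build_cycles, cycles_frame, DielCycle
from .stats import (
    bin_by_depth,
    compute_flr,
    flr_exceedance_test,
    flr_summary_by_unit,
    hourly_profile,
    wilcoxon_day_night,
)
from .synthetic import (
    LakeConfig,
    MetParams,
    SimScenario,
    TruthTable,
    default_scenario,
    render_sensor_records,
    simulate_flux_truth,
    simulate_met,
)
from .upscaling import (
    adjust_database,
    demo_database,
    diel_factor,
    read_database_csv,
    records_frame,
)

log = logging.getLogger("dielflux")

STAGES = ("simulate", "calibrate", "flux", "cycles", "flr", "drivers", "upscale")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 42
    scenario: dict = field(default_factory=dict)
    ambient_ppm: str | float = "met"  # "met" = background series from met table
    wind_threshold: float = 2.0
    endpoint_k: int = 3
    min_records: int = 5
    min_duration_h: float = 0.2
    day_window: tuple[float, float] = (10.0, 16.0)
    night_window: tuple[float, float] = (0.0, 4.0)
    r: str | float = "measured"  # day:night ratio for the diel factor
    upscaling_database: str | None = None

    def __post_init__(self) -> None:
        for name in ("day_window", "night_window"):
            w = tuple(getattr(self, name))
            if len(w) != 2 or not 0 <= w[0] < w[1] <= 24:
                raise ValueError(f"{name} must be (start, end) clock hours")
            setattr(self, name, w)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # location, not semantics: keep runs comparable
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def scenario_from_config(cfg: PipelineConfig) -> SimScenario:
    """Build the SimScenario from the config's ``scenario`` mapping.

    Lakes/chambers may be given explicitly; otherwise the default two-lake,
    five-chamber layout is used with any scalar overrides applied.
    """
    d = dict(cfg.scenario)
    met_d = dict(d.pop("met", {}))
    if "frontal_events" in met_d:
        met_d["frontal_events"] = tuple(tuple(e) for e in met_d["frontal_events"])
    if "cloud_factor_range" in met_d:
        met_d["cloud_factor_range"] = tuple(met_d["cloud_factor_range"])
    met = MetParams(**met_d)
    lakes_spec = d.pop("lakes", None)
    d.setdefault("rng_seed", cfg.seed)
    if lakes_spec is None:
        return default_scenario(**d, met=met)
    lakes = tuple(
        LakeConfig(
            **{k: v for k, v in lk.items() if k != "chambers"},
            chambers=tuple(ChamberSpec(**ch) for ch in lk["chambers"]),
        )
        for lk in lakes_spec
    )
    return SimScenario(lakes=lakes, met=met, **d)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def _span(scenario: SimScenario) -> tuple[pd.Timestamp, pd.Timestamp]:
    t0 = pd.Timestamp(scenario.start_date)
    return t0, t0 + pd.Timedelta(days=scenario.n_days + 1)


def build_all_cycles(scenario: SimScenario) -> dict[str, list[DielCycle]]:
    span = _span(scenario)
    return {lk.lake_id: build_cycles(lk, span) for lk in scenario.lakes}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on the configured synthetic scenario.

    Returns a bundle with the in-memory stage products; writes all file
    outputs plus ``manifest.json`` under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outputs": {}, "qc": {}}
    qc: dict[str, int] = {}

    def _outputs(stage: str, *paths: Path) -> None:
        bundle["outputs"][stage] = [str(p.relative_to(outdir)) for p in paths]

    # -- simulate -----------------------------------------------------------
    try:
        scenario = scenario_from_config(cfg)
        cycles = build_all_cycles(scenario)
        truth = simulate_flux_truth(scenario, cycles)
        met = simulate_met(scenario, cycles)
        series = render_sensor_records(truth, scenario, met, qc_log=qc)

        paths = []
        for s in series:
            p = outdir / "chambers" / f"{s.chamber_id}.csv"
            _write_csv(s.records, p)
            paths.append(p)
        for lake_id, m in met.items():
            p = outdir / f"met_{lake_id}.csv"
            _write_csv(m, p)
            paths.append(p)
        p_truth = outdir / "truth.csv"
        _write_csv(truth.data, p_truth)
        p_scen = outdir / "scenario.yaml"
        p_scen.write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=True))
        _outputs("simulate", *paths, p_truth, p_scen)
        bundle.update(scenario=scenario, cycles=cycles, truth=truth, met=met,
                      series=series)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # -- calibrate ----------------------------------------------------------
    try:
        series = impute_rh_temp(series)
        calibrations: dict[str, CalibrationModel] = {}
        for s in series:
            if s.geometry.kind != "automated":
                continue
            lake_met = met[s.lake_id].set_index("timestamp")
            ambient = (
                lake_met["ambient_ch4_ppm"]
                if cfg.ambient_ppm == "met"
                else float(cfg.ambient_ppm)
            )
            calibrations[s.chamber_id] = fit_calibration(
                s, ambient, lake_met["wind10_ms"], cfg.wind_threshold
            )
        p_cal = outdir / "calibrations.json"
        _write_json(
            {cid: dataclasses.asdict(c) for cid, c in calibrations.items()}, p_cal
        )
        _outputs("calibrate", p_cal)
        bundle["calibrations"] = calibrations
    except Exception as exc:  # noqa: BLE001
        raise StageError("calibrate", exc) from exc

    # -- flux ---------------------------------------------------------------
    try:
        records = []
        for s in series:
            pressure = met[s.lake_id].set_index("timestamp")["pressure_hpa"]
            if s.geometry.kind == "automated":
                records.extend(
                    compute_afc_flux(
                        s,
                        calibrations[s.chamber_id],
                        pressure,
                        k=cfg.endpoint_k,
                        min_records=cfg.min_records,
                        min_duration_h=cfg.min_duration_h,
                        qc_log=qc,
                    )
                )
            else:
                records.extend(manual_series_fluxes(s, pressure, qc_log=qc))
        fluxes = fluxes_frame(records)
        p_flux = outdir / "fluxes.csv"
        _write_csv(fluxes, p_flux)
        _outputs("flux", p_flux)
        bundle["fluxes"] = fluxes
    except Exception as exc:  # noqa: BLE001
        raise StageError("flux", exc) from exc

    # -- cycles -------------------------------------------------------------
    try:
        cyc_df = pd.concat(
            [cycles_frame(cs) for cs in cycles.values()], ignore_index=True
        )
        p_cyc = outdir / "cycles.csv"
        _write_csv(cyc_df, p_cyc)
        _outputs("cycles", p_cyc)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cycles", exc) from exc

    # -- flr (diel statistics) ---------------------------------------------
    try:
        profiles, tests = [], {}
        flr_frames = []
        for lake in scenario.lakes:
            lake_fluxes = fluxes[fluxes["lake_id"] == lake.lake_id]
            profiles.append(
                hourly_profile(lake_fluxes, lake.utc_offset, lake.lake_id,
                               lake.season_label)
            )
            test = wilcoxon_day_night(
                lake_fluxes, lake.utc_offset, cfg.day_window, cfg.night_window
            )
            tests[lake.lake_id] = dataclasses.asdict(test)
            flr_frames.append(compute_flr(lake_fluxes, cycles[lake.lake_id]))
        flr = pd.concat(flr_frames, ignore_index=True)

        depth_of = {
            ch.chamber_id: ch.depth_m for lk in scenario.lakes for ch in lk.chambers
        }
        flr["depth_m"] = flr["unit_id"].map(depth_of)
        bin_of = bin_by_depth(
            [ch for lk in scenario.lakes for ch in lk.chambers]
        )
        flr_bins = []
        for lake in scenario.lakes:
            flr_bins.append(
                compute_flr(
                    fluxes[fluxes["lake_id"] == lake.lake_id],
                    cycles[lake.lake_id],
                    unit_of=bin_of,
                )
            )
        flr_bin = pd.concat(flr_bins, ignore_index=True)
        tests["flr_exceedance"] = flr_exceedance_test(flr["FL_R"])

        p_flr = outdir / "flr.csv"
        p_flrb = outdir / "flr_depthbin.csv"
        p_prof = outdir / "hourly_profile.csv"
        p_tests = outdir / "tests.json"
        _write_csv(flr, p_flr)
        _write_csv(flr_bin, p_flrb)
        _write_csv(pd.concat(profiles, ignore_index=True), p_prof)
        _write_json(tests, p_tests)
        _outputs("flr", p_flr, p_flrb, p_prof, p_tests)
        bundle.update(flr=flr, flr_bin=flr_bin, tests=tests,
                      flr_by_unit=flr_summary_by_unit(flr))
    except Exception as exc:  # noqa: BLE001
        raise StageError("flr", exc) from exc

    # -- drivers ------------------------------------------------------------
    try:
        summaries = pd.concat(
            [
                driver_day_night_ratios(met[lk.lake_id], cycles[lk.lake_id])
                for lk in scenario.lakes
            ],
            ignore_index=True,
        )
        concordance = wind_flux_concordance(flr, summaries)
        pressure_sub = pressure_ratio_subset(summaries, flr)
        light = flr_vs_light(flr)
        correlations = {
            "wind_flux_concordance": concordance,
            "pressure_ratio_subset": {
                k: v for k, v in pressure_sub.items() if k != "subset"
            },
            "flr_vs_light": {k: v for k, v in light.items() if k != "pairs"},
        }
        p_drv = outdir / "drivers.csv"
        p_corr = outdir / "correlations.json"
        p_light = outdir / "flr_vs_light.csv"
        _write_csv(summaries, p_drv)
        _write_json(correlations, p_corr)
        _write_csv(light["pairs"], p_light)
        _outputs("drivers", p_drv, p_corr, p_light)
        bundle.update(driver_summaries=summaries, correlations=correlations)
    except Exception as exc:  # noqa: BLE001
        raise StageError("drivers", exc) from exc

    # -- upscale ------------------------------------------------------------
    try:
        if cfg.r == "measured":
            r = float(flr["FL_R"].dropna().mean())
        else:
            r = float(cfg.r)
        factor = diel_factor(r)
        database = (
            read_database_csv(cfg.upscaling_database)
            if cfg.upscaling_database
            else demo_database()
        )
        adjusted, summary = adjust_database(database, factor)
        p_adj = outdir / "upscaling_adjusted.csv"
        p_sum = outdir / "upscaling_summary.json"
        _write_csv(records_frame(adjusted), p_adj)
        _write_json(summary, p_sum)
        _outputs("upscale", p_adj, p_sum)
        bundle.update(diel_factor=factor, upscaling_summary=summary)
    except Exception as exc:  # noqa: BLE001
        raise StageError("upscale", exc) from exc

    bundle["qc"] = qc
    n_flux_excluded = sum(
        v for k, v in qc.items() if k.startswith(("closure_", "manual_"))
    )
    manifest = {
        "dielflux_version": __version__,
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "stages": list(bundle["outputs"]),
        "outputs": bundle["outputs"],
        "qc_exclusions": qc,
        "n_flux_records": int(len(fluxes)),
        "n_flux_excluded": int(n_flux_excluded),
        "diel_factor": {"r": factor.ratio_r, "factor": factor.factor},
    }
    _write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# input validation

CHAMBER_SCHEMA = ("timestamp", "rh_pct", "temp_c", "state")
MET_SCHEMA = (
    "timestamp", "air_temp_c", "pressure_hpa", "wind10_ms",
    "par_umol_m2_s", "water_temp_c",
)


def validate_inputs(paths: dict[str, list[str] | str]) -> dict:
    """Schema/range/monotonicity checks with row-level diagnostics.

    ``paths`` maps "chambers" to chamber-record CSVs and "met" to hourly
    meteorology CSVs.  Hard schema violations fail the file outright.
    """
    report: dict = {"ok": True, "files": {}}

    def _fail(name: str, msg: str) -> None:
        report["files"].setdefault(name, []).append(msg)
        report["ok"] = False

    for path in [paths.get("chambers", [])] if isinstance(
        paths.get("chambers", []), str
    ) else paths.get("chambers", []):
        name = str(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            _fail(name, f"unreadable: {exc}")
            continue
        missing = set(CHAMBER_SCHEMA) - set(df.columns)
        if missing:
            _fail(name, f"missing columns: {sorted(missing)}")
            continue
        if not ("raw_signal" in df.columns or "ch4_ppm" in df.columns):
            _fail(name, "need raw_signal or ch4_ppm column")
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        if ts.isna().any():
            _fail(name, f"unparseable timestamps at rows {list(ts[ts.isna()].index[:5])}")
        elif not ts.is_monotonic_increasing or ts.duplicated().any():
            bad = ts[ts.diff() <= pd.Timedelta(0)]
            _fail(name, f"timestamps not strictly increasing at rows {list(bad.index[:5])}")
        bad_rh = df[(df["rh_pct"] < 0) | (df["rh_pct"] > 100)]
        if len(bad_rh):
            _fail(name, f"rh_pct outside [0, 100] at rows {list(bad_rh.index[:5])}")
        bad_t = df[(df["temp_c"] < -60) | (df["temp_c"] > 60)]
        if len(bad_t):
            _fail(name, f"temp_c outside [-60, 60] at rows {list(bad_t.index[:5])}")
        bad_state = df[~df["state"].isin(["open", "closed"])]
        if len(bad_state):
            _fail(name, f"invalid state at rows {list(bad_state.index[:5])}")
        report["files"].setdefault(name, [])

    for path in [paths.get("met", [])] if isinstance(paths.get("met", []), str) else paths.get("met", []):
        name = str(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            _fail(name, f"unreadable: {exc}")
            continue
        missing = set(MET_SCHEMA) - set(df.columns)
        if missing:
            _fail(name, f"missing columns: {sorted(missing)}")
            continue
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        if ts.isna().any() or not ts.is_monotonic_increasing:
            _fail(name, "timestamps unparseable or not increasing")
        if (df["pressure_hpa"] < 800).any() or (df["pressure_hpa"] > 1100).any():
            _fail(name, "pressure_hpa outside plausible [800, 1100] hPa")
        if (df["wind10_ms"] < 0).any():
            _fail(name, "negative wind speed")
        if (df["par_umol_m2_s"] < 0).any():
            _fail(name, "negative PAR")
        report["files"].setdefault(name, [])

    return report
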