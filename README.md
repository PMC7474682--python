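# dielflux

Diel (24-h day/night) analysis of lake CH₄ chamber fluxes: from chamber
headspace concentration time series to fluxes, sunrise-anchored diel cycles,
day:night flux ratios (FL_R), driver diagnostics, and the diel correction
factor for lake-emission upscaling. A synthetic-data generator with known
ground truth makes every downstream stage testable without field data.

## Modules

| Module | What it does |
| --- | --- |
| `dielflux.synthetic` | Generates minute-resolution flux ground truth (multiplicative day/night pattern with configurable ratio, lognormal AR(1) noise, Poisson/exponential ebullition steps), hourly meteorological forcing, and renders the chamber measurement process (closure/flush cycles, raw sensor signal through an invertible calibration, manual grab samples). |
| `dielflux.chamber` | Sensor calibration (signal + absolute humidity vs background reference under well-mixed conditions), RH/temperature imputation, and per-closure endpoint-difference fluxes in µmol m⁻² h⁻¹ via the ideal gas law, with QC screening. |
| `dielflux.solar` | NOAA-equation sunrise/sunset (−0.833° elevation), sunrise-to-sunrise diel cycle segmentation, proportional day/night splitting of measurement intervals. |
| `dielflux.stats` | Time-weighted geometric hourly flux profiles, per-cycle duration-weighted FL_R, depth binning, rank-sum day-vs-night and signed-rank FL_R > 1 tests (exact small-sample nulls). |
| `dielflux.drivers` | Day:night ratios of wind / water temperature / ΔT / PAR, maximum 4-h moving-window pressure drops, similar-wind pressure subset, wind–flux concordance, FL_R vs light-period relation. |
| `dielflux.upscaling` | Diel factor (1 + 1/r)/2 (0.7 at r = 2.5) and its application to an emission database with per-type and overall reduction summaries. |
| `dielflux.pipeline` / `dielflux.cli` | Config, validation, orchestration, manifest, CLI. |

## CLI

```bash
# full synthetic pipeline (config optional; see below)
dielflux run --config config.yaml

# individual pieces
dielflux simulate --outdir out --seed 42
dielflux cycles --latitude 58.4 --longitude 14.6 --start 2018-09-01 --end 2018-09-11
dielflux upscale -r 2.5 --database emissions.csv
dielflux diel-factor 2.5
dielflux validate --chambers out/chambers/C1.csv --met out/met_L1.csv
```

Example `config.yaml`:

```yaml
outdir: out
seed: 42
scenario:
  n_days: 30
  r_true: 2.5
  flux_noise_sigma: 0.3
  ebullition_rate: 0.2
r: measured        # derive the diel factor from the recovered mean FL_R
```

Outputs under `outdir/`: per-chamber record CSVs, per-lake meteorology CSVs,
truth table, cycles, fluxes, FL_R (per chamber and per depth bin), hourly
profiles, test summaries, driver tables/correlations, adjusted emission
database, and `manifest.json` (seed, config digest, QC exclusion counts).
Runs are byte-identical under a fixed seed.

## Notes

- ppm is treated as µmol CH₄ per mol air; flux conversion uses
  R = 8.314 J mol⁻¹ K⁻¹ with closure-mean headspace temperature and pressure.
- Endpoint differencing (not regression) is used per closure so episodic
  ebullition steps are retained in the flux.
- Non-positive fluxes are excluded from geometric means (counts reported);
  FL_R uses arithmetic duration-weighted day/night means.
- Latitudes poleward of 66.5° (polar day/night) are unsupported by design.
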