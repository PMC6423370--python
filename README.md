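# phenosync

Data management for distributed field phenotyping.

In a crop field trial, each experimental plot carries one genotype /
treatment / replicate combination, and a subset of plots is monitored by
low-cost in-field workstations: a camera plus microclimate sensors (ambient
temperature and humidity, light, soil temperature, soil moisture) on a
single-board computer. Genotype-by-environment analysis needs the per-plot
imagery and per-plot climate co-registered in one place — but field
networking is unreliable and camera frames are often unusable (dark,
blown-out, truncated).

`phenosync` implements the full device-to-server pipeline for such a
deployment, plus a simulator so everything runs with no hardware:

- **Device agent** — scores each day's captures on file size, mean
  intensity, and clarity (variance of the 3×3 Laplacian of the grayscale
  image, the standard no-reference sharpness proxy), selects the single
  daily representative as the maximum-clarity image among those passing the
  size/intensity gates, and downsizes it from capture resolution
  (2,592 × 1,944) to 640 × 480 by exact area-averaged resampling. Every
  sync builds one JSON payload — status, the sensor-reading delta since the
  last acknowledged instant, at most one representative image — signed with
  HMAC-SHA-256 under the device's pre-shared key. If the server is
  unreachable, payloads queue in a FIFO store-and-forward buffer
  (60-day retention) and drain oldest-first on reconnection.
- **Collation server** — authenticates every payload before parsing,
  ingests idempotently (replaying any payload changes nothing), classifies
  device health as green / amber / red from the reported mode and the
  silence time relative to the expected 30-minute update cadence, accounts
  uptime and storage, and assembles the grid / device views. Exports are
  deterministic: sensor readings as CSV, images as monthly Zip archives.
  A stdlib HTTP facade exposes `POST /api/v1/sync` and the view/export
  endpoints.
- **Climate analytics** — fills the unmonitored plots of the grid by
  inverse-distance weighting (power 2) over the sensor plots,

  `v(x) = Σᵢ wᵢ(x) vᵢ,  wᵢ(x) ∝ ‖x − xᵢ‖⁻²,  Σᵢ wᵢ = 1`,

  which is exact at sensor plots, bounded by the measured range, and
  translation-equivariant; builds heat-map series at 14-day intervals with
  sensor plots outlined red and interpolated plots green; cross-validates
  the sensor network leave-one-out; and detects late-blight risk
  ("Smith Periods": ≥ 2 consecutive days, each with daily minimum
  temperature ≥ 10 °C and ≥ 11 hours of relative humidity ≥ 90%).
- **Field simulator** — seeded diurnal weather (sinusoidal temperature,
  anti-phase humidity, solar half-sine light, lagged/damped soil
  temperature), procedural canopy-like imagery with controllable sharpness
  and exposure, and whole-deployment runs with injectable network outages
  and device failures. One pseudo-random stream per device and variable, so
  adding a device never perturbs the others' data.

## Worked example

```python
from datetime import datetime, timezone
import phenosync as ps

store = ps.init_store(":memory:")
server = ps.CollationServer(store)

# 32 genotype plots on a 4x8 grid, 16 of them monitored
exp, devices = ps.standard_layout(store, grid_rows=4, grid_cols=8,
                                  n_monitored=16, capture_width=324,
                                  capture_height=243, seed=1)
transcript = ps.simulate_device_run(server, "exp-2017", days=7,
                                    weather=ps.WeatherModel(seed=1),
                                    images_per_day=3)
t = transcript.totals()
print(len(devices), t.representatives, t.payloads_sent)
# -> 16 112 2688        (16 devices x 7 days = 112 daily representatives,
#                         16 x 7 x 24 hourly payloads all delivered)

at = datetime(2017, 5, 4, 12, tzinfo=timezone.utc)
grid = ps.interpolate_plot_grid(store, "exp-2017", "ambient_temp_C", at)
print(grid.values.shape, int(grid.measured_mask.sum()))
# -> (4, 8) 16          (16 sensor plots measured, 16 plots interpolated)

table, rmse = ps.loo_validation(store, "exp-2017", "ambient_temp_C", at)
print(round(rmse, 3))
# -> 0.125              (leave-one-out RMSE across the 16 sensors, degC)

# a warm, persistently humid spell triggers the late-blight rule
frame = ps.simulate_weather(ps.WeatherModel(seed=1, mean_temp_C=16,
                                            rh_base_pct=90,
                                            rh_diurnal_amplitude_pct=8),
                            days=10)
for p in ps.detect_smith_periods(frame["ambient_temp_C"],
                                 frame["rel_humidity_pct"]):
    print(p.start_day, p.end_day, p.n_days)
# -> 2017-05-01 2017-05-03 3   (one 3-day risk period)
```

The same flows are scriptable from the shell: `phenosync simulate`,
`phenosync serve`, `phenosync heatmap`, `phenosync smith`,
`phenosync export-csv` (see `phenosync --help`).

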