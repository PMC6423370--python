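"""Field simulator: synthetic weather, synthetic crop images, experiment
layouts, and whole-deployment runs with fault injection.

This stands in for a real deployment of in-field phenotyping workstations:
it generates diurnal microclimate series with noise, procedural
plant-canopy-like images with controllable sharpness and exposure, and
drives device agents against a collation server hour by hour, routing
payloads through the store-and-forward queue whenever a device is inside a
simulated network outage.

Reproducibility discipline: every stream of randomness is derived from a
master seed plus a stable per-device, per-variable key, so adding a device
to a simulation never perturbs the data of existing devices.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from . import imaging
from .agent import (
    AgentConfig,
    LocalTransport,
    SyncQueue,
    build_payload,
    enqueue_and_flush,
)
from .models import (
    Device,
    DeviceMode,
    Experiment,
    ImageRecord,
    Plot,
    SENSOR_VARIABLES,
    SensorReading,
    StatusSnapshot,
    parse_utc,
    to_utc,
)
from .server import CollationServer
from .store import Store

#: Default simulation start: beginning of a northern growing season.
DEFAULT_START = datetime(2017, 5, 1, tzinfo=timezone.utc)

#: Hour of day (0-23) at which the diurnal temperature sinusoid peaks.
TEMP_PEAK_HOUR = 14

#: Daylight window for the solar half-sine, hours of day.
SUNRISE_HOUR, SUNSET_HOUR = 6, 18
MAX_LIGHT_LUX = 60_000.0


@dataclass(frozen=True)
class WeatherModel:
    """Closed-form diurnal weather with additive seeded noise.

    Ambient temperature is a sinusoid around ``mean_temp_C`` (amplitude
    ``diurnal_amplitude_C``, daily minimum at 02:00, maximum at 14:00)
    plus a linear seasonal trend.  Relative humidity runs in anti-phase
    with temperature.  Light is a solar half-sine, zero at night.  Soil
    temperature is ambient lagged by ``soil_lag_h`` hours and damped
    toward the seasonal baseline by ``soil_damping``.  All noise is
    i.i.d. Gaussian per variable; humidity and soil moisture are clipped
    to [0, 100] afterwards.
    """

    mean_temp_C: float = 15.0
    diurnal_amplitude_C: float = 5.0
    seasonal_trend_C_per_day: float = 0.05
    rh_base_pct: float = 75.0
    rh_diurnal_amplitude_pct: float = 15.0
    soil_lag_h: int = 2
    soil_damping: float = 0.5
    soil_moisture_base_pct: float = 35.0
    noise_sd: dict = dc_field(
        default_factory=lambda: {
            "ambient_temp_C": 0.5,
            "rel_humidity_pct": 3.0,
            "light_lux": 2000.0,
            "soil_temp_C": 0.3,
            "soil_moisture_pct": 1.5,
            "device_temp_C": 0.5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diurnal_amplitude_C < 0 or self.rh_diurnal_amplitude_pct < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 < self.soil_damping <= 1.0:
            raise ValueError("soil_damping must be in (0, 1]")


def _var_rng(seed: int, variable: str) -> np.random.Generator:
    key = int.from_bytes(hashlib.sha256(variable.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_weather(
    model: WeatherModel, days: int, start: datetime = DEFAULT_START
) -> pd.DataFrame:
    """Hourly series for all sensor variables: 24*days rows, one column per
    variable, UTC DatetimeIndex starting at ``start``.  The same seed
    always yields the identical frame."""
    if days < 1:
        raise ValueError("days must be >= 1")
    n = 24 * days
    hours = np.arange(n)
    hour_of_day = hours % 24
    day_idx = hours // 24
    phase = np.sin(2 * np.pi * (hour_of_day - (TEMP_PEAK_HOUR - 6)) / 24)

    baseline = model.mean_temp_C + model.seasonal_trend_C_per_day * day_idx
    noise = {
        v: (
            _var_rng(model.seed, v).normal(0.0, sd, n)
            if sd > 0
            else np.zeros(n)
        )
        for v, sd in model.noise_sd.items()
    }

    temp = baseline + model.diurnal_amplitude_C * phase + noise["ambient_temp_C"]
    rh = np.clip(
        model.rh_base_pct
        - model.rh_diurnal_amplitude_pct * phase
        + noise["rel_humidity_pct"],
        0.0,
        100.0,
    )
    solar = np.where(
        (hour_of_day >= SUNRISE_HOUR) & (hour_of_day <= SUNSET_HOUR),
        np.sin(np.pi * (hour_of_day - SUNRISE_HOUR) / (SUNSET_HOUR - SUNRISE_HOUR)),
        0.0,
    )
    light = np.clip(MAX_LIGHT_LUX * solar + noise["light_lux"] * solar, 0.0, None)
    lag = model.soil_lag_h
    temp_lagged = np.concatenate([np.full(lag, temp[0] if n else 0.0), temp])[:n]
    baseline_lagged = np.concatenate([np.full(lag, baseline[0]), baseline])[:n]
    soil_temp = (
        baseline
        + model.soil_damping * (temp_lagged - baseline_lagged)
        + noise["soil_temp_C"]
    )
    soil_moist = np.clip(
        model.soil_moisture_base_pct + noise["soil_moisture_pct"], 0.0, 100.0
    )
    device_temp = temp + 8.0 + noise["device_temp_C"]

    index = pd.date_range(to_utc(start), periods=n, freq="h", tz="UTC")
    return pd.DataFrame(
        {
            "ambient_temp_C": temp,
            "rel_humidity_pct": rh,
            "light_lux": light,
            "soil_temp_C": soil_temp,
            "soil_moisture_pct": soil_moist,
            "device_temp_C": device_temp,
        },
        index=index,
    )


# -- synthetic imagery -----------------------------------------------------


def synth_image(
    width: int,
    height: int,
    sharpness: float,
    exposure: float,
    seed: int,
) -> bytes:
    """Procedural canopy-like test image, PNG-encoded.

    A smooth large-scale blob texture (leaf masses) is overlaid with fine
    detail whose amplitude grows with ``sharpness``; overall brightness
    scales with ``exposure``.  For a fixed seed, clarity is strictly
    increasing in sharpness and mean intensity increasing in exposure.
    Byte-deterministic in all arguments.
    """
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    sharpness = float(np.clip(sharpness, 0.0, 1.0))
    exposure = float(np.clip(exposure, 0.0, 1.0))
    rng = np.random.default_rng(np.random.SeedSequence([seed, width, height]))
    block = 32
    coarse = rng.random(((height // block) + 2, (width // block) + 2))
    smooth = np.kron(coarse, np.ones((block, block)))[:height, :width]
    smooth = ndimage.uniform_filter(smooth, size=block + 1)
    fine = rng.standard_normal((height, width))
    base = exposure * (60.0 + 160.0 * smooth)
    detail = sharpness * 45.0 * exposure * fine
    pixels = np.clip(base + detail, 0.0, 255.0).astype(np.uint8)
    # green-tinted RGB so the fixture resembles a crop canopy
    rgb = np.stack(
        [
            (pixels * 0.55).astype(np.uint8),
            pixels,
            (pixels * 0.45).astype(np.uint8),
        ],
        axis=-1,
    )
    buf = io.BytesIO()
    Image.fromarray(rgb, mode="RGB").save(buf, format="PNG", compress_level=1)
    return buf.getvalue()


# -- experiment layout -----------------------------------------------------


def standard_layout(
    store: Store,
    experiment_id: str = "exp-2017",
    grid_rows: int = 4,
    grid_cols: int = 8,
    n_monitored: int = 16,
    capture_width: int = 2592,
    capture_height: int = 1944,
    start: datetime = DEFAULT_START,
    seed: int = 0,
) -> tuple[Experiment, list[Device]]:
    """Register the standard simulated trial: a grid of genotype plots of
    which ``n_monitored`` carry a phenotyping workstation (default: 16
    monitored among 32 plots).  Device shared keys are derived from the
    seed; the choice of monitored plots is seeded too."""
    n_plots = grid_rows * grid_cols
    if n_monitored > n_plots:
        raise ValueError("more devices than plots")
    exp = Experiment(
        experiment_id=experiment_id,
        name="simulated field trial",
        latitude=52.62,
        longitude=1.22,
        start_date=start.date(),
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        description="synthetic plot-grid trial generated by the field simulator",
    )
    store.add_experiment(exp)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFACE]))
    monitored = set(rng.choice(n_plots, size=n_monitored, replace=False).tolist())
    devices = []
    for i in range(n_plots):
        r, c = divmod(i, grid_cols)
        device_id = f"dev-{i:03d}" if i in monitored else None
        plot = Plot(
            plot_id=f"plot-{r}{c}",
            experiment_id=experiment_id,
            row=r,
            col=c,
            genotype=f"genotype-{i % 32:02d}",
            treatment="control",
            replicate=1 + i // 32,
            drilling_date=start.date(),
            device_id=device_id,
        )
        store.add_plot(plot)
        if device_id is not None:
            key = hashlib.sha256(f"key:{seed}:{device_id}".encode()).digest()
            dev = Device(
                device_id=device_id,
                shared_key=key,
                plot_id=plot.plot_id,
                boot_time=start,
                capture_width=capture_width,
                capture_height=capture_height,
            )
            store.add_device(dev)
            devices.append(dev)
    return exp, devices


# -- fault injection -------------------------------------------------------


@dataclass(frozen=True)
class FaultSchedule:
    """Declarative faults for a run: network outage windows per device and
    permanent mode failures at an instant.  Faults are data, not errors."""

    outages: tuple = ()  # (device_id, start, end)
    failures: tuple = ()  # (device_id, instant, DeviceMode)

    def __post_init__(self) -> None:
        for device_id, start, end in self.outages:
            if not start < end:
                raise ValueError(f"outage for {device_id} has start >= end")

    def is_offline(self, device_id: str, at: datetime) -> bool:
        return any(
            d == device_id and start <= at < end for d, start, end in self.outages
        )

    def mode_at(self, device_id: str, at: datetime) -> DeviceMode:
        mode = DeviceMode.OPERATING
        when = None
        for d, instant, failed_mode in self.failures:
            if d == device_id and instant <= at and (when is None or instant > when):
                mode, when = failed_mode, instant
        return mode


# -- full deployment run ---------------------------------------------------


@dataclass
class DeviceTranscript:
    payloads_built: int = 0
    payloads_sent: int = 0
    payloads_queued: int = 0
    payloads_dropped: int = 0
    images_captured: int = 0
    representatives: int = 0


@dataclass
class RunTranscript:
    devices: dict[str, DeviceTranscript] = dc_field(default_factory=dict)

    def totals(self) -> DeviceTranscript:
        t = DeviceTranscript()
        for d in self.devices.values():
            t.payloads_built += d.payloads_built
            t.payloads_sent += d.payloads_sent
            t.payloads_queued += d.payloads_queued
            t.payloads_dropped += d.payloads_dropped
            t.images_captured += d.images_captured
            t.representatives += d.representatives
        return t


def _capture_hours(images_per_day: int) -> list[int]:
    """Daylight capture schedule: hours evenly spread across 9..15."""
    if images_per_day == 1:
        return [12]
    return [
        int(round(9 + 6 * i / (images_per_day - 1))) for i in range(images_per_day)
    ]


def simulate_device_run(
    server: CollationServer,
    experiment_id: str,
    days: int,
    weather: WeatherModel = WeatherModel(),
    images_per_day: int = 3,
    faults: FaultSchedule = FaultSchedule(),
    start: datetime = DEFAULT_START,
    sync_interval_h: int = 1,
    agent_config: AgentConfig = AgentConfig(),
    bad_frame_rate: float = 0.0,
) -> RunTranscript:
    """Drive every registered device of an experiment for ``days`` simulated
    days against ``server``.

    Each device, each day: logs 24 hourly readings per variable, captures
    ``images_per_day`` synthetic photos, closes the day by selecting and
    downsizing one representative, and syncs hourly — through the
    store-and-forward queue whenever its outage windows make the server
    unreachable.  Mode failures switch the reported device mode from their
    instant onward.  Fully deterministic given (layout, weather seed,
    fault schedule).
    """
    start = to_utc(start)
    transcript = RunTranscript()
    exp = server.store.get_experiment(experiment_id)
    device_ids = [
        p.device_id for p in server.store.plots_for_experiment(experiment_id)
        if p.device_id is not None
    ]
    capture_hours = _capture_hours(images_per_day)
    for device_id in device_ids:
        dt = transcript.devices.setdefault(device_id, DeviceTranscript())
        device = server.store.get_device(device_id)
        dev_seed_key = int.from_bytes(
            hashlib.sha256(device_id.encode()).digest()[:4], "big"
        )
        dev_seed = int(
            np.random.SeedSequence([weather.seed, dev_seed_key]).generate_state(1)[0]
            % (2**31)
        )
        dev_weather = WeatherModel(**{**weather.__dict__, "seed": dev_seed})
        series = simulate_weather(dev_weather, days, start)
        cap_rng = np.random.default_rng(np.random.SeedSequence([dev_seed, 0xCA0]))

        local = Store(":memory:")
        local.add_experiment(exp)
        local.add_device(device)
        queue = SyncQueue()
        cursor = start - timedelta(seconds=1)
        acked_images: list[datetime] = []
        target_w = min(640, device.capture_width)
        target_h = target_w * 3 // 4
        selection = imaging.SelectionConfig(
            target_width=target_w, target_height=target_h
        )
        day_captures: list[ImageRecord] = []

        for h in range(24 * days):
            ts = start + timedelta(hours=h)
            hour_of_day = ts.hour
            mode = faults.mode_at(device_id, ts)
            local.record_readings(
                [
                    SensorReading(device_id, var, ts, float(series.iloc[h][var]))
                    for var in SENSOR_VARIABLES
                ]
            )
            local.record_status(
                StatusSnapshot(
                    device_id=device_id,
                    timestamp=ts,
                    cpu_pct=float(cap_rng.uniform(5, 60)),
                    mem_pct=float(cap_rng.uniform(20, 70)),
                    storage_free_gb=max(0.0, 64.0 - 0.5 * (h / 24)),
                    storage_total_gb=64.0,
                    mode=mode,
                )
            )
            if hour_of_day in capture_hours:
                sharp = float(cap_rng.uniform(0.2, 1.0))
                expo = float(cap_rng.uniform(0.35, 0.85))
                if cap_rng.random() < bad_frame_rate:  # black/failed frame
                    expo = 0.02
                content = synth_image(
                    device.capture_width, device.capture_height, sharp, expo,
                    seed=int(cap_rng.integers(0, 2**31)),
                )
                score = imaging.score_image(content)
                day_captures.append(
                    ImageRecord(
                        device_id=device_id,
                        capture_time=ts,
                        width=device.capture_width,
                        height=device.capture_height,
                        file_size=score.file_size,
                        mean_intensity=score.mean_intensity,
                        clarity=score.clarity,
                        content=content,
                    )
                )
                dt.images_captured += 1
            if hour_of_day == 23:  # close the calendar day
                chosen = imaging.select_representative(day_captures, selection)
                if chosen is not None:
                    small = imaging.downsample_image(
                        chosen.content, target_w, target_h
                    )
                    rescored = imaging.score_image(small)
                    local.record_image(
                        ImageRecord(
                            device_id=device_id,
                            capture_time=chosen.capture_time,
                            width=target_w,
                            height=target_h,
                            file_size=rescored.file_size,
                            mean_intensity=rescored.mean_intensity,
                            clarity=rescored.clarity,
                            content=small,
                            is_representative=True,
                        )
                    )
                    dt.representatives += 1
                day_captures = []
            if (h + 1) % sync_interval_h == 0:
                now = ts  # sync at the top of the hour, after logging
                payload = build_payload(
                    local, device_id, since=cursor, now=now,
                    acked_images=acked_images,
                )
                doc = payload.to_document(device.shared_key)
                cursor = now
                dt.payloads_built += 1
                transport = LocalTransport(
                    server, reachable=not faults.is_offline(device_id, now)
                )
                report = enqueue_and_flush(queue, doc, transport, now, agent_config)
                dt.payloads_sent += len(report.sent)
                dt.payloads_dropped += report.dropped
                if report.queued:
                    dt.payloads_queued += 1
                for ack in report.sent:
                    if ack.get("accepted") and ack.get("image_ack"):
                        acked_images.append(parse_utc(ack["image_ack"]))
    return transcript
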