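"""Domain types shared by the device agent, the collation server and the
analytics layer.

A field experiment is a rectangular grid of plots (0-based, row-major,
row 0 = north edge).  Each plot carries its experimental-design metadata
(genotype, treatment, replicate) and at most one monitoring device.  A
device logs hourly microclimate readings, captures crop images during the
day, and once a day closes, selects a single representative image.

All timestamps are timezone-aware UTC and are serialized as ISO-8601 with
second resolution and a trailing ``Z``; equality for deduplication is at
second resolution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Optional

UTC_FORMAT = "%Y-%m-%dT%H:%M:%SZ"

#: Sensor variables a device reports, with their units encoded in the name.
SENSOR_VARIABLES = (
    "ambient_temp_C",
    "rel_humidity_pct",
    "light_lux",
    "soil_temp_C",
    "soil_moisture_pct",
    "device_temp_C",
)

#: Default capture resolution of the plot camera, in pixels.
CAPTURE_WIDTH = 2592
CAPTURE_HEIGHT = 1944

#: Resolution of the daily representative image shipped to the server.
REPRESENTATIVE_WIDTH = 640
REPRESENTATIVE_HEIGHT = 480


class ValidationError(ValueError):
    """A domain invariant was violated while constructing a record."""


def utc_now() -> datetime:
    return datetime.now(timezone.utc).replace(microsecond=0)


def to_utc(ts: datetime) -> datetime:
    """Coerce a datetime to timezone-aware UTC at second resolution."""
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).replace(microsecond=0)


def format_utc(ts: datetime) -> str:
    return to_utc(ts).strftime(UTC_FORMAT)


def parse_utc(s: str) -> datetime:
    return datetime.strptime(s, UTC_FORMAT).replace(tzinfo=timezone.utc)


class DeviceMode(str, enum.Enum):
    OPERATING = "operating"
    IDLE = "idle"
    ERROR = "error"
    TERMINATED = "terminated"


class StatusColor(str, enum.Enum):
    """Traffic-light freshness/health classification of a device.

    Green means the device is operating and syncing on schedule, amber
    means it is idle or moderately late, red means it reported an error or
    termination, or has been silent for so long it must be presumed dead.
    """

    GREEN = "green"
    AMBER = "amber"
    RED = "red"


@dataclass(frozen=True)
class Experiment:
    experiment_id: str
    name: str
    latitude: float
    longitude: float
    start_date: date
    grid_rows: int
    grid_cols: int
    end_date: Optional[date] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid dimensions must be >= 1")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")
        if self.end_date is not None and self.start_date > self.end_date:
            raise ValidationError("start_date after end_date")


@dataclass(frozen=True)
class Plot:
    plot_id: str
    experiment_id: str
    row: int
    col: int
    genotype: str
    treatment: str = ""
    replicate: int = 1
    drilling_date: Optional[date] = None
    device_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValidationError("grid coordinates are 0-based and non-negative")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass(frozen=True)
class Device:
    device_id: str
    shared_key: bytes
    plot_id: str
    boot_time: datetime
    capture_width: int = CAPTURE_WIDTH
    capture_height: int = CAPTURE_HEIGHT
    mode: DeviceMode = DeviceMode.OPERATING

    def __post_init__(self) -> None:
        if not self.shared_key:
            raise ValidationError("shared_key must be non-empty")
        if self.capture_width <= 0 or self.capture_height <= 0:
            raise ValidationError("capture dimensions must be positive")
        object.__setattr__(self, "boot_time", to_utc(self.boot_time))


@dataclass(frozen=True)
class SensorReading:
    device_id: str
    variable: str
    timestamp: datetime
    value: float

    def __post_init__(self) -> None:
        if self.variable not in SENSOR_VARIABLES:
            raise ValidationError(f"unknown sensor variable {self.variable!r}")
        if self.variable in ("rel_humidity_pct", "soil_moisture_pct"):
            if not 0.0 <= self.value <= 100.0:
                raise ValidationError(
                    f"{self.variable} value {self.value} outside [0, 100]"
                )
        object.__setattr__(self, "timestamp", to_utc(self.timestamp))

    @property
    def key(self) -> tuple:
        """The dedupe key: one reading per device, variable and second."""
        return (self.device_id, self.variable, format_utc(self.timestamp))


@dataclass(frozen=True)
class ImageRecord:
    device_id: str
    capture_time: datetime
    width: int
    height: int
    file_size: int
    mean_intensity: float
    clarity: float
    content: bytes
    is_representative: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("image dimensions must be positive")
        if not 0.0 <= self.mean_intensity <= 255.0:
            raise ValidationError("mean_intensity outside [0, 255]")
        if self.clarity < 0.0:
            raise ValidationError("clarity must be non-negative")
        object.__setattr__(self, "capture_time", to_utc(self.capture_time))


@dataclass(frozen=True)
class StatusSnapshot:
    device_id: str
    timestamp: datetime
    cpu_pct: float
    mem_pct: float
    storage_free_gb: float
    storage_total_gb: float
    mode: DeviceMode = DeviceMode.OPERATING

    def __post_init__(self) -> None:
        for name in ("cpu_pct", "mem_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} {v} outside [0, 100]")
        if self.storage_total_gb <= 0:
            raise ValidationError("storage_total_gb must be positive")
        if self.storage_free_gb < 0 or self.storage_free_gb > self.storage_total_gb:
            raise ValidationError("storage_free_gb outside [0, storage_total_gb]")
        object.__setattr__(self, "timestamp", to_utc(self.timestamp))


@dataclass(frozen=True)
class StatusClassification:
    device_id: str
    color: StatusColor
    reason: str
    as_of: datetime


@dataclass(frozen=True)
class RiskPeriod:
    """A maximal run of consecutive qualifying risk days (inclusive ends)."""

    start_day: date
    end_day: date
    rule: str = "smith"

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValidationError("end_day before start_day")

    @property
    def n_days(self) -> int:
        return (self.end_day - self.start_day).days + 1
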