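"""Shared fixtures: a small monitored plot grid with registered devices,
and builders for readings, statuses and scored image records."""

from __future__ import annotations

from datetime import date, datetime, timezone

import pytest

from phenosync.models import (
    Device,
    Experiment,
    ImageRecord,
    Plot,
    SensorReading,
    StatusSnapshot,
)
from phenosync.server import CollationServer
from phenosync.store import Store, init_store

UTC = timezone.utc


def dt(*args) -> datetime:
    return datetime(*args, tzinfo=UTC)


START = dt(2017, 5, 1)

#: (row, col) -> device_id for the default 3x3 fixture field.
MONITORED = {(0, 0): "dev-a", (0, 2): "dev-b", (2, 1): "dev-c"}


def make_field(
    store: Store | None = None,
    grid: tuple[int, int] = (3, 3),
    monitored: dict[tuple[int, int], str] = MONITORED,
) -> tuple[Store, dict[tuple[int, int], str]]:
    """A grid experiment with a device on each ``monitored`` plot; keys are
    ``b"key-" + device_id``."""
    store = store or init_store(":memory:")
    store.add_experiment(
        Experiment(
            experiment_id="exp",
            name="fixture trial",
            latitude=52.62,
            longitude=1.22,
            start_date=date(2017, 5, 1),
            grid_rows=grid[0],
            grid_cols=grid[1],
        )
    )
    for r in range(grid[0]):
        for c in range(grid[1]):
            device_id = monitored.get((r, c))
            store.add_plot(
                Plot(
                    plot_id=f"p{r}{c}",
                    experiment_id="exp",
                    row=r,
                    col=c,
                    genotype=f"g{r}{c}",
                    device_id=device_id,
                )
            )
            if device_id:
                store.add_device(
                    Device(
                        device_id=device_id,
                        shared_key=b"key-" + device_id.encode(),
                        plot_id=f"p{r}{c}",
                        boot_time=START,
                    )
                )
    return store, monitored


@pytest.fixture
def field():
    store, monitored = make_field()
    return store


@pytest.fixture
def server(field):
    return CollationServer(field)


def reading(device_id: str, hour: int, value: float,
            variable: str = "ambient_temp_C") -> SensorReading:
    """Reading ``hour`` whole hours after 2017-05-01T00:00Z."""
    from datetime import timedelta

    return SensorReading(
        device_id=device_id,
        variable=variable,
        timestamp=START + timedelta(hours=hour),
        value=value,
    )


def status(device_id: str, ts: datetime, mode="operating",
           free_gb: float = 32.0, total_gb: float = 64.0) -> StatusSnapshot:
    from phenosync.models import DeviceMode

    return StatusSnapshot(
        device_id=device_id,
        timestamp=ts,
        cpu_pct=10.0,
        mem_pct=40.0,
        storage_free_gb=free_gb,
        storage_total_gb=total_gb,
        mode=DeviceMode(mode),
    )


def scored_image(
    device_id: str,
    ts: datetime,
    file_size: int = 1000,
    mean_intensity: float = 120.0,
    clarity: float = 10.0,
    content: bytes = b"\x89PNG\r\n\x1a\nfixture",
    is_representative: bool = False,
) -> ImageRecord:
    """An image record with prescribed scores; content is a stand-in blob
    (selection and storage never re-decode it)."""
    return ImageRecord(
        device_id=device_id,
        capture_time=ts,
        width=640,
        height=480,
        file_size=file_size,
        mean_intensity=mean_intensity,
        clarity=clarity,
        content=content,
        is_representative=is_representative,
    )
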