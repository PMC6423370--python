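"""Relational store shared by the device agent and the collation server.

The same schema backs both sides: on a device it holds the locally captured
data awaiting synchronization, on the server it holds the collated data for
every registered device.  SQLite is used directly; the schema is small and
fixed, and every write goes through a method on :class:`Store`.

Exports are pure functions of store content: two stores holding identical
data yield byte-identical CSV and Zip documents (fixed dialect, fixed
compression, fixed archive entry timestamps).
"""

from __future__ import annotations

import csv
import hashlib
import io
import sqlite3
import zipfile
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .models import (
    Device,
    DeviceMode,
    Experiment,
    ImageRecord,
    Plot,
    SensorReading,
    StatusSnapshot,
    ValidationError,
    format_utc,
    parse_utc,
)

CSV_HEADER = ["device_id", "variable", "timestamp_utc", "value"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS experiments (
    experiment_id TEXT PRIMARY KEY,
    name TEXT NOT NULL,
    latitude REAL NOT NULL,
    longitude REAL NOT NULL,
    start_date TEXT NOT NULL,
    end_date TEXT,
    grid_rows INTEGER NOT NULL,
    grid_cols INTEGER NOT NULL,
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS plots (
    plot_id TEXT PRIMARY KEY,
    experiment_id TEXT NOT NULL REFERENCES experiments(experiment_id),
    row INTEGER NOT NULL,
    col INTEGER NOT NULL,
    genotype TEXT NOT NULL,
    treatment TEXT NOT NULL DEFAULT '',
    replicate INTEGER NOT NULL DEFAULT 1,
    drilling_date TEXT,
    device_id TEXT,
    UNIQUE (experiment_id, row, col)
);
CREATE TABLE IF NOT EXISTS devices (
    device_id TEXT PRIMARY KEY,
    shared_key BLOB NOT NULL,
    plot_id TEXT NOT NULL,
    boot_time TEXT NOT NULL,
    capture_width INTEGER NOT NULL,
    capture_height INTEGER NOT NULL,
    mode TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS readings (
    device_id TEXT NOT NULL REFERENCES devices(device_id),
    variable TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    value REAL NOT NULL,
    PRIMARY KEY (device_id, variable, timestamp)
);
CREATE INDEX IF NOT EXISTS idx_readings_device_ts
    ON readings(device_id, timestamp);
CREATE TABLE IF NOT EXISTS images (
    device_id TEXT NOT NULL REFERENCES devices(device_id),
    capture_time TEXT NOT NULL,
    width INTEGER NOT NULL,
    height INTEGER NOT NULL,
    file_size INTEGER NOT NULL,
    mean_intensity REAL NOT NULL,
    clarity REAL NOT NULL,
    is_representative INTEGER NOT NULL DEFAULT 0,
    content BLOB NOT NULL,
    PRIMARY KEY (device_id, capture_time)
);
CREATE TABLE IF NOT EXISTS status_snapshots (
    device_id TEXT NOT NULL REFERENCES devices(device_id),
    timestamp TEXT NOT NULL,
    cpu_pct REAL NOT NULL,
    mem_pct REAL NOT NULL,
    storage_free_gb REAL NOT NULL,
    storage_total_gb REAL NOT NULL,
    mode TEXT NOT NULL,
    PRIMARY KEY (device_id, timestamp)
);
"""


class StorageError(RuntimeError):
    """The backing path could not be opened or written."""


class ReferentialError(KeyError):
    """A record referenced a device or experiment that is not registered."""


def init_store(path: str | Path) -> "Store":
    """Open (creating if necessary) a store at ``path``.

    Idempotent: re-opening an existing store leaves its data intact.
    ``":memory:"`` gives a private transient store.
    """
    return Store(path)


class Store:
    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        try:
            # check_same_thread off: the HTTP facade serves from worker
            # threads; sqlite3's serialized mode makes this safe for our use
            self._conn = sqlite3.connect(self.path, check_same_thread=False)
        except sqlite3.OperationalError as exc:
            raise StorageError(f"cannot open store at {self.path}: {exc}") from exc
        self._conn.row_factory = sqlite3.Row
        try:
            self._conn.executescript(_SCHEMA)
            self._conn.commit()
        except sqlite3.OperationalError as exc:
            raise StorageError(f"cannot initialize store at {self.path}: {exc}") from exc

    def close(self) -> None:
        self._conn.close()

    # -- registration ------------------------------------------------------

    def add_experiment(self, exp: Experiment) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO experiments VALUES (?,?,?,?,?,?,?,?,?)",
            (
                exp.experiment_id,
                exp.name,
                exp.latitude,
                exp.longitude,
                exp.start_date.isoformat(),
                exp.end_date.isoformat() if exp.end_date else None,
                exp.grid_rows,
                exp.grid_cols,
                exp.description,
            ),
        )
        self._conn.commit()

    def add_plot(self, plot: Plot) -> None:
        exp = self.get_experiment(plot.experiment_id)
        if not (plot.row < exp.grid_rows and plot.col < exp.grid_cols):
            raise ValidationError(
                f"plot ({plot.row}, {plot.col}) outside "
                f"{exp.grid_rows}x{exp.grid_cols} grid"
            )
        if plot.device_id is not None:
            taken = self._conn.execute(
                "SELECT plot_id FROM plots WHERE device_id = ? AND plot_id != ?",
                (plot.device_id, plot.plot_id),
            ).fetchone()
            if taken:
                raise ValidationError(
                    f"device {plot.device_id} already assigned to plot {taken[0]}"
                )
        try:
            self._conn.execute(
                "INSERT OR REPLACE INTO plots VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    plot.plot_id,
                    plot.experiment_id,
                    plot.row,
                    plot.col,
                    plot.genotype,
                    plot.treatment,
                    plot.replicate,
                    plot.drilling_date.isoformat() if plot.drilling_date else None,
                    plot.device_id,
                ),
            )
        except sqlite3.IntegrityError as exc:
            raise ValidationError(str(exc)) from exc
        self._conn.commit()

    def add_device(self, dev: Device) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO devices VALUES (?,?,?,?,?,?,?)",
            (
                dev.device_id,
                dev.shared_key,
                dev.plot_id,
                format_utc(dev.boot_time),
                dev.capture_width,
                dev.capture_height,
                dev.mode.value,
            ),
        )
        self._conn.commit()

    # -- lookups -----------------------------------------------------------

    def get_experiment(self, experiment_id: str) -> Experiment:
        row = self._conn.execute(
            "SELECT * FROM experiments WHERE experiment_id = ?", (experiment_id,)
        ).fetchone()
        if row is None:
            raise ReferentialError(f"unknown experiment {experiment_id!r}")
        return Experiment(
            experiment_id=row["experiment_id"],
            name=row["name"],
            latitude=row["latitude"],
            longitude=row["longitude"],
            start_date=date.fromisoformat(row["start_date"]),
            end_date=date.fromisoformat(row["end_date"]) if row["end_date"] else None,
            grid_rows=row["grid_rows"],
            grid_cols=row["grid_cols"],
            description=row["description"],
        )

    def list_experiments(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT experiment_id FROM experiments ORDER BY experiment_id"
        ).fetchall()
        return [r[0] for r in rows]

    def get_device(self, device_id: str) -> Device:
        row = self._conn.execute(
            "SELECT * FROM devices WHERE device_id = ?", (device_id,)
        ).fetchone()
        if row is None:
            raise ReferentialError(f"unknown device {device_id!r}")
        return Device(
            device_id=row["device_id"],
            shared_key=row["shared_key"],
            plot_id=row["plot_id"],
            boot_time=parse_utc(row["boot_time"]),
            capture_width=row["capture_width"],
            capture_height=row["capture_height"],
            mode=DeviceMode(row["mode"]),
        )

    def list_devices(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT device_id FROM devices ORDER BY device_id"
        ).fetchall()
        return [r[0] for r in rows]

    def plots_for_experiment(self, experiment_id: str) -> list[Plot]:
        rows = self._conn.execute(
            "SELECT * FROM plots WHERE experiment_id = ? ORDER BY row, col",
            (experiment_id,),
        ).fetchall()
        return [
            Plot(
                plot_id=r["plot_id"],
                experiment_id=r["experiment_id"],
                row=r["row"],
                col=r["col"],
                genotype=r["genotype"],
                treatment=r["treatment"],
                replicate=r["replicate"],
                drilling_date=(
                    date.fromisoformat(r["drilling_date"]) if r["drilling_date"] else None
                ),
                device_id=r["device_id"],
            )
            for r in rows
        ]

    # -- sensor readings ---------------------------------------------------

    def record_readings(self, readings: Iterable[SensorReading]) -> int:
        """Insert readings, silently skipping duplicates of the dedupe key
        (device, variable, timestamp).  Returns the count newly inserted."""
        readings = list(readings)
        known = {r[0] for r in self._conn.execute("SELECT device_id FROM devices")}
        for r in readings:
            if r.device_id not in known:
                raise ReferentialError(f"unknown device {r.device_id!r}")
        before = self._count("readings")
        self._conn.executemany(
            "INSERT OR IGNORE INTO readings VALUES (?,?,?,?)",
            [
                (r.device_id, r.variable, format_utc(r.timestamp), r.value)
                for r in readings
            ],
        )
        self._conn.commit()
        return self._count("readings") - before

    def readings_for(
        self,
        device_id: str,
        start: Optional[datetime] = None,
        end: Optional[datetime] = None,
        variable: Optional[str] = None,
    ) -> list[SensorReading]:
        q = "SELECT * FROM readings WHERE device_id = ?"
        args: list = [device_id]
        if start is not None:
            q += " AND timestamp > ?"
            args.append(format_utc(start))
        if end is not None:
            q += " AND timestamp <= ?"
            args.append(format_utc(end))
        if variable is not None:
            q += " AND variable = ?"
            args.append(variable)
        q += " ORDER BY timestamp, variable"
        return [
            SensorReading(
                device_id=r["device_id"],
                variable=r["variable"],
                timestamp=parse_utc(r["timestamp"]),
                value=r["value"],
            )
            for r in self._conn.execute(q, args)
        ]

    def latest_reading_time(self, device_id: str) -> Optional[datetime]:
        row = self._conn.execute(
            "SELECT MAX(timestamp) FROM readings WHERE device_id = ?", (device_id,)
        ).fetchone()
        return parse_utc(row[0]) if row[0] else None

    # -- images ------------------------------------------------------------

    def record_image(self, image: ImageRecord) -> bool:
        """Store an image; returns False if one already exists at the same
        (device, capture second)."""
        self.get_device(image.device_id)
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO images VALUES (?,?,?,?,?,?,?,?,?)",
            (
                image.device_id,
                format_utc(image.capture_time),
                image.width,
                image.height,
                image.file_size,
                image.mean_intensity,
                image.clarity,
                int(image.is_representative),
                image.content,
            ),
        )
        self._conn.commit()
        return cur.rowcount == 1

    def images_for(
        self,
        device_id: str,
        start: Optional[datetime] = None,
        end: Optional[datetime] = None,
        representative_only: bool = False,
    ) -> list[ImageRecord]:
        q = "SELECT * FROM images WHERE device_id = ?"
        args: list = [device_id]
        if start is not None:
            q += " AND capture_time >= ?"
            args.append(format_utc(start))
        if end is not None:
            q += " AND capture_time < ?"
            args.append(format_utc(end))
        if representative_only:
            q += " AND is_representative = 1"
        q += " ORDER BY capture_time"
        return [self._row_to_image(r) for r in self._conn.execute(q, args)]

    def latest_representative(self, device_id: str) -> Optional[ImageRecord]:
        row = self._conn.execute(
            "SELECT * FROM images WHERE device_id = ? AND is_representative = 1 "
            "ORDER BY capture_time DESC LIMIT 1",
            (device_id,),
        ).fetchone()
        return self._row_to_image(row) if row else None

    def latest_image_time(self, device_id: str) -> Optional[datetime]:
        row = self._conn.execute(
            "SELECT MAX(capture_time) FROM images WHERE device_id = ?", (device_id,)
        ).fetchone()
        return parse_utc(row[0]) if row[0] else None

    @staticmethod
    def _row_to_image(r: sqlite3.Row) -> ImageRecord:
        return ImageRecord(
            device_id=r["device_id"],
            capture_time=parse_utc(r["capture_time"]),
            width=r["width"],
            height=r["height"],
            file_size=r["file_size"],
            mean_intensity=r["mean_intensity"],
            clarity=r["clarity"],
            is_representative=bool(r["is_representative"]),
            content=r["content"],
        )

    # -- status snapshots --------------------------------------------------

    def record_status(self, snap: StatusSnapshot) -> bool:
        self.get_device(snap.device_id)
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO status_snapshots VALUES (?,?,?,?,?,?,?)",
            (
                snap.device_id,
                format_utc(snap.timestamp),
                snap.cpu_pct,
                snap.mem_pct,
                snap.storage_free_gb,
                snap.storage_total_gb,
                snap.mode.value,
            ),
        )
        self._conn.commit()
        return cur.rowcount == 1

    def latest_status(self, device_id: str) -> Optional[StatusSnapshot]:
        row = self._conn.execute(
            "SELECT * FROM status_snapshots WHERE device_id = ? "
            "ORDER BY timestamp DESC LIMIT 1",
            (device_id,),
        ).fetchone()
        if row is None:
            return None
        return StatusSnapshot(
            device_id=row["device_id"],
            timestamp=parse_utc(row["timestamp"]),
            cpu_pct=row["cpu_pct"],
            mem_pct=row["mem_pct"],
            storage_free_gb=row["storage_free_gb"],
            storage_total_gb=row["storage_total_gb"],
            mode=DeviceMode(row["mode"]),
        )

    # -- exports -----------------------------------------------------------

    def export_sensor_csv(
        self,
        device_id: str,
        start: Optional[datetime] = None,
        end: Optional[datetime] = None,
    ) -> str:
        """Comma-separated export of a device's readings, sorted by timestamp
        then variable.  Header always present; an empty range yields a
        header-only document.  LF line endings, ``.`` decimal point."""
        self.get_device(device_id)
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        q = "SELECT * FROM readings WHERE device_id = ?"
        args: list = [device_id]
        if start is not None:
            q += " AND timestamp >= ?"
            args.append(format_utc(start))
        if end is not None:
            q += " AND timestamp <= ?"
            args.append(format_utc(end))
        q += " ORDER BY timestamp, variable"
        for r in self._conn.execute(q, args):
            writer.writerow(
                [r["device_id"], r["variable"], r["timestamp"], repr(r["value"])]
            )
        return buf.getvalue()

    def export_monthly_archive(self, device_id: str, year: int, month: int) -> bytes:
        """Zip archive of every image captured by ``device_id`` in the given
        calendar month.  Entries are named
        ``<device_id>/<YYYYMMDDTHHMMSSZ>.png`` and round-trip byte-exact.
        A month with no images yields an empty but valid archive."""
        self.get_device(device_id)
        start = datetime(year, month, 1, tzinfo=None)
        if month == 12:
            end = datetime(year + 1, 1, 1)
        else:
            end = datetime(year, month + 1, 1)
        images = self.images_for(device_id, start=start, end=end)
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED, compresslevel=6) as zf:
            for img in images:
                ext = "png" if img.content[:8] == b"\x89PNG\r\n\x1a\n" else "jpg"
                stamp = img.capture_time.strftime("%Y%m%dT%H%M%SZ")
                info = zipfile.ZipInfo(
                    filename=f"{device_id}/{stamp}.{ext}",
                    # fixed entry mtime: archives depend only on store content
                    date_time=(1980, 1, 1, 0, 0, 0),
                )
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, img.content)
        return buf.getvalue()

    # -- bookkeeping -------------------------------------------------------

    def _count(self, table: str) -> int:
        return self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def counts(self) -> dict[str, int]:
        return {
            t: self._count(t)
            for t in ("experiments", "plots", "devices", "readings", "images",
                      "status_snapshots")
        }

    def content_checksum(self) -> str:
        """Order-independent digest of all stored data (used to prove that
        view assembly and exports never mutate the store)."""
        h = hashlib.sha256()
        for table in ("experiments", "plots", "devices", "readings", "images",
                      "status_snapshots"):
            rows = self._conn.execute(f"SELECT * FROM {table}").fetchall()
            for row in sorted(repr(tuple(r)) for r in rows):
                h.update(row.encode())
        return h.hexdigest()
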