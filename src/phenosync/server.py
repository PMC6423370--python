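"""Server-side collation: authenticated ingestion of device sync payloads,
device health classification, and assembly of the grid/list/individual
monitoring views.

Every sync document is authenticated against the device's pre-shared key
before anything is parsed or stored, and ingestion is idempotent: readings
pass through the dedupe key, images and status snapshots are keyed by
(device, instant), so replaying any payload changes nothing.  The server
acknowledges each payload with the highest ingested reading timestamp so
the agent can advance its delta cursor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Any, Optional

from .models import (
    Device,
    DeviceMode,
    StatusClassification,
    StatusColor,
    format_utc,
)
from .payload import MalformedPayloadError, parse_document, verify
from .store import ReferentialError, Store

logger = logging.getLogger(__name__)

#: Expected status/sensor refresh cadence, minutes (the shipped default).
DEFAULT_CADENCE_MIN = 30
#: Silence beyond this many cadences turns a device amber.
AMBER_AFTER_CADENCES = 2
#: Silence beyond this many cadences turns a device red.
RED_AFTER_CADENCES = 6


class ClockSkewError(RuntimeError):
    """The latest image predates the reported boot time."""


@dataclass(frozen=True)
class Rejection:
    reason: str  # unknown_device | auth_failure | malformed


@dataclass(frozen=True)
class IngestReport:
    device_id: str
    readings_inserted: int
    image_stored: bool
    status_recorded: bool
    ack_through: datetime
    image_ack: Optional[datetime] = None


def storage_percent(storage_free_gb: float, storage_total_gb: float) -> float:
    """Percentage of onboard storage still free, one-decimal rounding."""
    if storage_total_gb <= 0:
        raise ValueError("storage_total_gb must be positive")
    return round(100.0 * storage_free_gb / storage_total_gb, 1)


class CollationServer:
    """Central collation endpoint over a :class:`~phenosync.store.Store`.

    The store doubles as the device/key registry: a payload from a device
    that was never registered is rejected before signature verification.
    """

    def __init__(self, store: Store, cadence_min: int = DEFAULT_CADENCE_MIN):
        self.store = store
        self.cadence = timedelta(minutes=cadence_min)

    # -- ingestion ---------------------------------------------------------

    def authenticate_payload(self, document: dict[str, Any]) -> Optional[Rejection]:
        """Accept (``None``) iff the document's signature verifies under the
        registered key of the claimed device; otherwise a Rejection that
        leaves the store untouched."""
        device_id = document.get("device_id")
        try:
            device = self.store.get_device(str(device_id))
        except ReferentialError:
            return Rejection("unknown_device")
        if not verify(document, device.shared_key):
            return Rejection("auth_failure")
        return None

    def ingest_payload(self, document: dict[str, Any]) -> IngestReport | Rejection:
        """Parse and store an authenticated payload, all-or-nothing.

        A malformed document is rejected with nothing stored.  Replays are
        harmless: the report then shows 0 new readings and no new image,
        and the status snapshot is recognized rather than duplicated.
        """
        try:
            payload = parse_document(document)
        except MalformedPayloadError as exc:
            logger.warning("rejecting malformed payload: %s", exc)
            return Rejection("malformed")
        n_inserted = self.store.record_readings(list(payload.readings))
        image_stored = False
        image_ack = None
        if payload.image is not None:
            image_stored = self.store.record_image(payload.image)
            image_ack = payload.image.capture_time
        self.store.record_status(payload.status)
        ack_through = max(
            (r.timestamp for r in payload.readings), default=payload.since
        )
        logger.info(
            "ingested %s: %d readings, image=%s", payload.device_id, n_inserted,
            image_stored,
        )
        return IngestReport(
            device_id=payload.device_id,
            readings_inserted=n_inserted,
            image_stored=image_stored,
            status_recorded=True,
            ack_through=ack_through,
            image_ack=image_ack,
        )

    def handle_sync(self, document: dict[str, Any]) -> dict[str, Any]:
        """The POST /sync entry point: authenticate, then ingest; returns
        the JSON-able ack (or rejection) document."""
        rejection = self.authenticate_payload(document)
        if rejection is None:
            result = self.ingest_payload(document)
        else:
            result = rejection
        if isinstance(result, Rejection):
            logger.warning("rejected sync from %r: %s",
                           document.get("device_id"), result.reason)
            return {"accepted": False, "reason": result.reason}
        return {
            "accepted": True,
            "device_id": result.device_id,
            "readings_inserted": result.readings_inserted,
            "image_stored": result.image_stored,
            "ack_through": format_utc(result.ack_through),
            "image_ack": format_utc(result.image_ack) if result.image_ack else None,
        }

    # -- monitoring --------------------------------------------------------

    def classify_device_status(
        self, device_id: str, now: datetime
    ) -> StatusClassification:
        """Traffic-light health of a device at instant ``now``.

        Red: last reported mode is error/terminated, silence beyond six
        cadences, or no contact ever.  Amber: mode idle, or silence beyond
        two cadences.  Green otherwise.  Monotone in silence: a device
        never improves by staying quiet.
        """
        snap = self.store.latest_status(device_id)
        if snap is None:
            return StatusClassification(device_id, StatusColor.RED, "no_contact", now)
        silence = now - snap.timestamp
        if snap.mode in (DeviceMode.ERROR, DeviceMode.TERMINATED):
            return StatusClassification(
                device_id, StatusColor.RED, f"mode_{snap.mode.value}", now
            )
        if silence > RED_AFTER_CADENCES * self.cadence:
            return StatusClassification(
                device_id, StatusColor.RED, "silent_too_long", now
            )
        if snap.mode == DeviceMode.IDLE:
            return StatusClassification(device_id, StatusColor.AMBER, "mode_idle", now)
        if silence > AMBER_AFTER_CADENCES * self.cadence:
            return StatusClassification(device_id, StatusColor.AMBER, "silent", now)
        return StatusClassification(device_id, StatusColor.GREEN, "operating", now)

    def compute_uptime(self, device_id: str) -> timedelta:
        """Experiment duration of a device: latest image capture time minus
        boot time; zero before the first capture.  A capture that predates
        boot is a clock-skew error, reported rather than clamped."""
        device = self.store.get_device(device_id)
        latest = self.store.latest_image_time(device_id)
        if latest is None:
            return timedelta(0)
        if latest < device.boot_time:
            raise ClockSkewError(
                f"latest capture {format_utc(latest)} predates boot "
                f"{format_utc(device.boot_time)}"
            )
        return latest - device.boot_time

    # -- views -------------------------------------------------------------

    def assemble_grid_view(self, experiment_id: str, now: datetime) -> dict[str, Any]:
        """The experiment overview: geolocation, the plot map with per-plot
        genotype/device/status color, and each device's latest
        representative image reference.  Read-only and pure."""
        exp = self.store.get_experiment(experiment_id)
        cells = []
        for plot in self.store.plots_for_experiment(experiment_id):
            cell: dict[str, Any] = {
                "plot_id": plot.plot_id,
                "row": plot.row,
                "col": plot.col,
                "genotype": plot.genotype,
                "treatment": plot.treatment,
                "replicate": plot.replicate,
                "monitored": plot.device_id is not None,
                "device_id": plot.device_id,
                "status_color": None,
                "representative_image": None,
            }
            if plot.device_id is not None:
                cls = self.classify_device_status(plot.device_id, now)
                cell["status_color"] = cls.color.value
                cell["status_reason"] = cls.reason
                rep = self.store.latest_representative(plot.device_id)
                if rep is not None:
                    cell["representative_image"] = {
                        "capture_time": format_utc(rep.capture_time),
                        "width": rep.width,
                        "height": rep.height,
                    }
            cells.append(cell)
        return {
            "experiment_id": exp.experiment_id,
            "name": exp.name,
            "latitude": exp.latitude,
            "longitude": exp.longitude,
            "grid_rows": exp.grid_rows,
            "grid_cols": exp.grid_cols,
            "as_of": format_utc(now),
            "plots": cells,
        }

    def assemble_device_view(
        self, device_id: str, start: datetime, end: datetime
    ) -> dict[str, Any]:
        """The individual-device detail: info, health, uptime, storage, and
        per-variable hourly series over ``(start, end]`` ready for chart
        rendering.  Hours with no reading carry an explicit ``None`` —
        gaps are shown, never interpolated here."""
        device = self.store.get_device(device_id)
        snap = self.store.latest_status(device_id)
        cls = self.classify_device_status(device_id, end)
        readings = self.store.readings_for(device_id, start=start, end=end)
        by_var: dict[str, dict[str, float]] = {}
        for r in readings:
            by_var.setdefault(r.variable, {})[format_utc(r.timestamp)] = r.value
        n_hours = int((end - start).total_seconds() // 3600)
        lattice = [start + timedelta(hours=h + 1) for h in range(n_hours)]
        series = {
            var: [
                {"timestamp": format_utc(t), "value": vals.get(format_utc(t))}
                for t in lattice
            ]
            for var, vals in sorted(by_var.items())
        }
        try:
            uptime_s = self.compute_uptime(device_id).total_seconds()
        except ClockSkewError:
            uptime_s = None
        return {
            "device_id": device_id,
            "plot_id": device.plot_id,
            "mode": (snap.mode.value if snap else device.mode.value),
            "status_color": cls.color.value,
            "status_reason": cls.reason,
            "uptime_seconds": uptime_s,
            "storage_free_pct": (
                storage_percent(snap.storage_free_gb, snap.storage_total_gb)
                if snap
                else None
            ),
            "from": format_utc(start),
            "to": format_utc(end),
            "series": series,
        }
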