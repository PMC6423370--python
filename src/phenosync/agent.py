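"""Device-side behavior: daily capture and selection, payload assembly at
the sync cadence, and store-and-forward buffering across network outages.

A field device keeps its own local :class:`~phenosync.store.Store` as a
server node.  Every sync interval it builds one signed payload (status +
reading delta + at most one new representative image) and hands it to
:func:`enqueue_and_flush`: if the server is unreachable the payload is
persisted in a FIFO queue; on reconnection the queue is drained
oldest-first before the current payload goes out.  The onboard buffer
retains 60 days of data by default — older queued payloads are dropped
with a warning, mirroring the capacity of the device's local storage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Optional, Protocol, Sequence

from .models import format_utc, parse_utc
from .payload import SyncPayload
from .store import Store

logger = logging.getLogger(__name__)

#: Status/sensor refresh cadence of the shipped configuration, minutes.
DEFAULT_STATUS_INTERVAL_MIN = 30
#: Payload build/sync cadence of the shipped configuration, minutes.
DEFAULT_SYNC_INTERVAL_MIN = 60
#: Onboard store-and-forward retention horizon, days.
DEFAULT_RETENTION_DAYS = 60


@dataclass(frozen=True)
class AgentConfig:
    """Cadences and buffering limits of a device agent.

    ``status_interval_min`` is how often the device refreshes its status
    and sensor report (30 minutes in the shipped configuration);
    ``sync_interval_min`` is how often a payload is built and sent;
    ``retention_days`` bounds how long undelivered payloads are kept.
    """

    status_interval_min: int = DEFAULT_STATUS_INTERVAL_MIN
    sync_interval_min: int = DEFAULT_SYNC_INTERVAL_MIN
    retention_days: int = DEFAULT_RETENTION_DAYS
    max_queue_entries: Optional[int] = None


class TransportError(RuntimeError):
    """The server could not be reached."""


class Transport(Protocol):
    def send(self, document: dict[str, Any]) -> dict[str, Any]:
        """Deliver one sync document; returns the server's ack document.
        Raises :class:`TransportError` when the server is unreachable."""
        ...


class LocalTransport:
    """In-process delivery straight into a collation server object, with a
    switchable ``reachable`` flag for outage simulation."""

    def __init__(self, server, reachable: bool = True):
        self.server = server
        self.reachable = reachable

    def send(self, document: dict[str, Any]) -> dict[str, Any]:
        if not self.reachable:
            raise TransportError("server unreachable")
        return self.server.handle_sync(document)


def build_payload(
    store: Store,
    device_id: str,
    since: datetime,
    now: Optional[datetime] = None,
    acked_images: Sequence[datetime] = (),
) -> SyncPayload:
    """Assemble the device's next sync payload from its local store.

    Contains the latest status snapshot, every reading strictly after
    ``since`` (up to ``now`` when given), and the newest representative
    image whose capture time is not in ``acked_images``.
    """
    status = store.latest_status(device_id)
    if status is None:
        raise ValueError(f"no status snapshot recorded for {device_id}")
    readings = tuple(store.readings_for(device_id, start=since, end=now))
    acked = {format_utc(t) for t in acked_images}
    image = None
    for rep in reversed(store.images_for(device_id, representative_only=True)):
        if format_utc(rep.capture_time) not in acked:
            image = rep
            break
    return SyncPayload(
        device_id=device_id, since=since, status=status, readings=readings, image=image
    )


@dataclass
class QueueEntry:
    built_at: datetime
    document: dict[str, Any]


@dataclass
class DeliveryReport:
    sent: list[dict[str, Any]] = field(default_factory=list)  # acks, in order
    queued: bool = False
    dropped: int = 0


class SyncQueue:
    """FIFO buffer of undelivered sync documents.

    With a directory path the queue survives agent restarts (one JSON file
    per entry, sequence-numbered); without one it is in-memory.  Entries
    older than the retention horizon are dropped at flush time, and a full
    queue evicts its oldest entries first.
    """

    def __init__(self, directory: Optional[str | Path] = None):
        self.directory = Path(directory) if directory is not None else None
        self._entries: list[QueueEntry] = []
        self._seq = 0
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            for f in sorted(self.directory.glob("*.json")):
                data = json.loads(f.read_text())
                self._entries.append(
                    QueueEntry(parse_utc(data["built_at"]), data["document"])
                )
                self._seq = max(self._seq, int(f.stem) + 1)

    def __len__(self) -> int:
        return len(self._entries)

    def push(self, entry: QueueEntry, max_entries: Optional[int] = None) -> int:
        """Append an entry, evicting oldest-first if the queue is capped.
        Returns the number of evicted entries."""
        self._entries.append(entry)
        if self.directory is not None:
            path = self.directory / f"{self._seq:012d}.json"
            path.write_text(
                json.dumps(
                    {"built_at": format_utc(entry.built_at), "document": entry.document}
                )
            )
            self._paths = getattr(self, "_paths", {})
            self._paths[id(entry)] = path
        self._seq += 1
        evicted = 0
        while max_entries is not None and len(self._entries) > max_entries:
            oldest = self._entries.pop(0)
            self._discard_file(oldest)
            evicted += 1
            logger.warning("sync queue full: evicted payload built %s",
                           format_utc(oldest.built_at))
        return evicted

    def drop_expired(self, now: datetime, retention: timedelta) -> int:
        """Drop entries older than the retention horizon (oldest data the
        onboard buffer can still hold)."""
        keep, dropped = [], 0
        for e in self._entries:
            if now - e.built_at > retention:
                self._discard_file(e)
                dropped += 1
                logger.warning(
                    "dropping payload built %s: older than %s retention",
                    format_utc(e.built_at), retention,
                )
            else:
                keep.append(e)
        self._entries = keep
        return dropped

    def pop_oldest(self) -> QueueEntry:
        e = self._entries.pop(0)
        self._discard_file(e)
        return e

    def peek_all(self) -> list[QueueEntry]:
        return list(self._entries)

    def _discard_file(self, entry: QueueEntry) -> None:
        if self.directory is not None:
            path = getattr(self, "_paths", {}).pop(id(entry), None)
            if path is not None:
                path.unlink(missing_ok=True)
            else:  # entry loaded from disk on restart: match by content
                for f in sorted(self.directory.glob("*.json")):
                    data = json.loads(f.read_text())
                    if data["document"] == entry.document:
                        f.unlink()
                        break


def enqueue_and_flush(
    queue: SyncQueue,
    document: dict[str, Any],
    transport: Transport,
    now: datetime,
    config: AgentConfig = AgentConfig(),
) -> DeliveryReport:
    """Deliver one sync document with store-and-forward semantics.

    Unreachable server: the document joins the FIFO queue.  Reachable:
    the queue is drained oldest-first, then the current document is sent;
    each acknowledged document is removed.  Entries past the retention
    horizon are dropped first with a logged warning.
    """
    report = DeliveryReport()
    report.dropped += queue.drop_expired(now, timedelta(days=config.retention_days))
    while len(queue) > 0:
        entry = queue.peek_all()[0]
        try:
            ack = transport.send(entry.document)
        except TransportError:
            report.dropped += queue.push(
                QueueEntry(built_at=now, document=document),
                max_entries=config.max_queue_entries,
            )
            report.queued = True
            return report
        queue.pop_oldest()
        report.sent.append(ack)
    try:
        ack = transport.send(document)
        report.sent.append(ack)
    except TransportError:
        report.dropped += queue.push(
            QueueEntry(built_at=now, document=document),
            max_entries=config.max_queue_entries,
        )
        report.queued = True
    return report
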