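"""The signed JSON document a device POSTs to the collation server.

One sync = one document: the device's latest status snapshot, every sensor
reading strictly after the last acknowledged instant (``since``), and at
most one daily representative image (base64-embedded).  The document is
authenticated with an HMAC-SHA-256 of its canonical serialization under
the device's pre-shared key; canonical means keys sorted lexicographically
and no insignificant whitespace, so the signature is byte-stable.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
from dataclasses import dataclass
from datetime import datetime
from typing import Any, Optional

from .models import (
    DeviceMode,
    ImageRecord,
    SensorReading,
    StatusSnapshot,
    format_utc,
    parse_utc,
)


class MalformedPayloadError(ValueError):
    """The document is not a structurally valid sync payload."""


def canonical_json(doc: dict[str, Any]) -> bytes:
    """Deterministic serialization: sorted keys, compact separators, UTF-8."""
    return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode("utf-8")


def sign(doc: dict[str, Any], key: bytes) -> str:
    """Hex HMAC-SHA-256 over the canonical serialization of ``doc``
    (which must not itself contain a ``signature`` field)."""
    return hmac.new(key, canonical_json(doc), hashlib.sha256).hexdigest()


def verify(doc: dict[str, Any], key: bytes) -> bool:
    body = {k: v for k, v in doc.items() if k != "signature"}
    expected = sign(body, key)
    return hmac.compare_digest(expected, str(doc.get("signature", "")))


@dataclass(frozen=True)
class SyncPayload:
    device_id: str
    since: datetime
    status: StatusSnapshot
    readings: tuple[SensorReading, ...]
    image: Optional[ImageRecord] = None

    def to_document(self, key: bytes) -> dict[str, Any]:
        """Serialize and sign.  Serializing the same payload twice yields
        identical bytes and an identical signature."""
        doc: dict[str, Any] = {
            "device_id": self.device_id,
            "since": format_utc(self.since),
            "status": {
                "timestamp": format_utc(self.status.timestamp),
                "cpu_pct": self.status.cpu_pct,
                "mem_pct": self.status.mem_pct,
                "storage_free_gb": self.status.storage_free_gb,
                "storage_total_gb": self.status.storage_total_gb,
                "mode": self.status.mode.value,
            },
            "readings": [
                {
                    "variable": r.variable,
                    "timestamp": format_utc(r.timestamp),
                    "value": r.value,
                }
                for r in self.readings
            ],
        }
        if self.image is not None:
            doc["image"] = {
                "capture_time": format_utc(self.image.capture_time),
                "width": self.image.width,
                "height": self.image.height,
                "file_size": self.image.file_size,
                "mean_intensity": self.image.mean_intensity,
                "clarity": self.image.clarity,
                "content_b64": base64.b64encode(self.image.content).decode("ascii"),
            }
        doc["signature"] = sign(doc, key)
        return doc


def parse_document(doc: dict[str, Any]) -> SyncPayload:
    """Parse and validate a sync document (signature is NOT checked here;
    authentication is the server's separate first step).

    Raises :class:`MalformedPayloadError` on any structural defect, so a
    bad document is rejected before anything touches the store.
    """
    try:
        device_id = doc["device_id"]
        since = parse_utc(doc["since"])
        s = doc["status"]
        status = StatusSnapshot(
            device_id=device_id,
            timestamp=parse_utc(s["timestamp"]),
            cpu_pct=float(s["cpu_pct"]),
            mem_pct=float(s["mem_pct"]),
            storage_free_gb=float(s["storage_free_gb"]),
            storage_total_gb=float(s["storage_total_gb"]),
            mode=DeviceMode(s["mode"]),
        )
        readings = tuple(
            SensorReading(
                device_id=device_id,
                variable=r["variable"],
                timestamp=parse_utc(r["timestamp"]),
                value=float(r["value"]),
            )
            for r in doc["readings"]
        )
        image = None
        if doc.get("image") is not None:
            i = doc["image"]
            image = ImageRecord(
                device_id=device_id,
                capture_time=parse_utc(i["capture_time"]),
                width=int(i["width"]),
                height=int(i["height"]),
                file_size=int(i["file_size"]),
                mean_intensity=float(i["mean_intensity"]),
                clarity=float(i["clarity"]),
                content=base64.b64decode(i["content_b64"]),
                is_representative=True,
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise MalformedPayloadError(f"invalid sync document: {exc}") from exc
    for r in readings:
        if r.timestamp <= since:
            raise MalformedPayloadError(
                f"reading at {format_utc(r.timestamp)} not after since cursor"
            )
    return SyncPayload(
        device_id=device_id, since=since, status=status, readings=readings, image=image
    )
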