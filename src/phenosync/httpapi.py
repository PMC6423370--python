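"""Thin HTTP facade over the collation server, on the standard library.

Endpoints (JSON unless noted):

- ``POST /api/v1/sync`` — one signed sync document in, ack out
- ``GET  /api/v1/experiments/<id>/grid`` — the experiment grid view
- ``GET  /api/v1/devices/<id>/view?from=&to=`` — the device detail view
- ``GET  /api/v1/devices/<id>/sensors.csv`` — sensor readings as CSV
- ``GET  /api/v1/devices/<id>/images/<YYYY-MM>.zip`` — monthly image archive

The handler delegates every decision to :class:`CollationServer`; it adds
no logic of its own, so in-process tests of the server cover the HTTP
surface too.
"""

from __future__ import annotations

import json
import re
import threading
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Optional
from urllib.parse import parse_qs, urlparse

from .agent import TransportError
from .models import parse_utc
from .server import CollationServer
from .store import ReferentialError

_SYNC = re.compile(r"^/api/v1/sync$")
_GRID = re.compile(r"^/api/v1/experiments/([^/]+)/grid$")
_VIEW = re.compile(r"^/api/v1/devices/([^/]+)/view$")
_CSV = re.compile(r"^/api/v1/devices/([^/]+)/sensors\.csv$")
_ZIP = re.compile(r"^/api/v1/devices/([^/]+)/images/(\d{4})-(\d{2})\.zip$")


def make_handler(server: CollationServer):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, fmt, *args):  # quiet; server logs ingest itself
            pass

        def _send(self, code: int, body: bytes, ctype: str) -> None:
            self.send_response(code)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _json(self, code: int, doc: Any) -> None:
            self._send(code, json.dumps(doc).encode(), "application/json")

        def do_POST(self) -> None:
            if not _SYNC.match(urlparse(self.path).path):
                self._json(404, {"error": "not_found"})
                return
            length = int(self.headers.get("Content-Length", 0))
            try:
                document = json.loads(self.rfile.read(length))
            except json.JSONDecodeError:
                self._json(400, {"accepted": False, "reason": "malformed"})
                return
            ack = server.handle_sync(document)
            self._json(200 if ack.get("accepted") else 403, ack)

        def do_GET(self) -> None:
            parsed = urlparse(self.path)
            path, query = parsed.path, parse_qs(parsed.query)
            try:
                if m := _GRID.match(path):
                    now = parse_utc(query["as_of"][0]) if "as_of" in query else None
                    from .models import utc_now

                    self._json(
                        200, server.assemble_grid_view(m.group(1), now or utc_now())
                    )
                elif m := _VIEW.match(path):
                    self._json(
                        200,
                        server.assemble_device_view(
                            m.group(1),
                            parse_utc(query["from"][0]),
                            parse_utc(query["to"][0]),
                        ),
                    )
                elif m := _CSV.match(path):
                    csv_text = server.store.export_sensor_csv(m.group(1))
                    self._send(200, csv_text.encode(), "text/csv")
                elif m := _ZIP.match(path):
                    blob = server.store.export_monthly_archive(
                        m.group(1), int(m.group(2)), int(m.group(3))
                    )
                    self._send(200, blob, "application/zip")
                else:
                    self._json(404, {"error": "not_found"})
            except ReferentialError as exc:
                self._json(404, {"error": str(exc)})
            except (KeyError, ValueError) as exc:
                self._json(400, {"error": str(exc)})

    return Handler


class ApiServer:
    """A collation server bound to a local port; ``with ApiServer(...) as s``
    serves in a background thread."""

    def __init__(self, server: CollationServer, host: str = "127.0.0.1",
                 port: int = 0):
        self._httpd = ThreadingHTTPServer((host, port), make_handler(server))
        self._thread: Optional[threading.Thread] = None

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def __enter__(self) -> "ApiServer":
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True
        )
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def serve_forever(self) -> None:
        self._httpd.serve_forever()


class HttpTransport:
    """Agent-side transport that POSTs sync documents to a remote server."""

    def __init__(self, base_url: str, timeout: float = 10.0):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def send(self, document: dict[str, Any]) -> dict[str, Any]:
        req = urllib.request.Request(
            f"{self.base_url}/api/v1/sync",
            data=json.dumps(document).encode(),
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            # an HTTP response IS a reachable server: surface the rejection
            return json.loads(exc.read())
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise TransportError(f"server unreachable: {exc}") from exc
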