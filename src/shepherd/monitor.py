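"""Status snapshots, text status table, and a minimal JSON action endpoint.

The HTTP endpoint replaces a browser UI: ``GET /status`` returns the current
:class:`StatusSnapshot` as JSON, ``POST /action`` forwards one recovery or
release action to the engine.  All four failure-recovery actions (restart,
modify+restart, ignore, resolve) plus checkpoint and resource-hold releases
are reachable this way, headlessly.
"""

from __future__ import annotations

import json
import logging
import threading
import time
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .exceptions import SchedulerError, ShepherdError, TransitionError

logger = logging.getLogger(__name__)

_COUNTER_STATES = ("pending", "ready", "held_resource", "held_checkpoint", "running",
                   "succeeded", "failed_awaiting_user", "ignored", "resolved_manual",
                   "excluded")


@dataclass(frozen=True)
class StatusRow:
    task_id: int
    subtask_index: int
    module: str
    state: str
    attempt: int
    host: str | None
    exit_code: int | None


@dataclass(frozen=True)
class StatusSnapshot:
    rows: tuple[StatusRow, ...]
    counters: dict[str, int]
    timestamp: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "counters": self.counters,
                "rows": [vars(r) for r in self.rows],
            },
            sort_keys=True,
        )


def snapshot(engine) -> StatusSnapshot:
    """Consistent point-in-time view of all subtasks; counters equal row tallies."""
    with engine._lock:
        rows = []
        for key in sorted(engine.records):
            rec = engine.records[key]
            task = engine.spec.task_by_ref(rec.task_id)
            rows.append(
                StatusRow(rec.task_id, rec.subtask_index, task.module_ref,
                          rec.state.name.lower(), rec.attempt, rec.host, rec.exit_code)
            )
    counters = {s: 0 for s in _COUNTER_STATES}
    for r in rows:
        counters[r.state] = counters.get(r.state, 0) + 1
    return StatusSnapshot(tuple(rows), counters, time.time())


def render_table(snap: StatusSnapshot) -> str:
    header = f"{'subtask':>9}  {'module':<18} {'state':<22} {'att':>3} {'host':<8} {'exit':>4}"
    lines = [header, "-" * len(header)]
    for r in snap.rows:
        lines.append(
            f"{r.task_id}-{r.subtask_index:>2}".rjust(9)
            + f"  {r.module:<18} {r.state:<22} {r.attempt:>3} "
            + f"{(r.host or '-'):<8} {('-' if r.exit_code is None else r.exit_code):>4}"
        )
    busy = {k: v for k, v in snap.counters.items() if v}
    lines.append("counters: " + " ".join(f"{k}={v}" for k, v in sorted(busy.items())))
    return "\n".join(lines)


class _Handler(BaseHTTPRequestHandler):
    engine = None

    def log_message(self, fmt, *args):  # route through logging, not stderr
        logger.debug("status-server: " + fmt, *args)

    def _send(self, code: int, payload: dict | str):
        body = (payload if isinstance(payload, str) else json.dumps(payload)).encode()
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self):
        if self.path.rstrip("/") in ("", "/status"):
            self._send(200, snapshot(self.engine).to_json())
        else:
            self._send(404, {"error": f"unknown path {self.path}"})

    def do_POST(self):
        if self.path.rstrip("/") != "/action":
            self._send(404, {"error": f"unknown path {self.path}"})
            return
        try:
            length = int(self.headers.get("Content-Length", "0"))
            payload = json.loads(self.rfile.read(length) or b"{}")
            task = int(payload["task"])
            subtask = int(payload.get("subtask", 0))
            action = payload["action"]
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            self._send(400, {"error": f"bad action payload: {exc}"})
            return
        try:
            applied = self.engine.act(
                task, subtask, action,
                params=payload.get("params"), returns=payload.get("returns"),
            )
        except TransitionError as exc:
            self._send(409, {"error": str(exc)})
            return
        except (SchedulerError, ShepherdError) as exc:
            self._send(404, {"error": str(exc)})
            return
        self._send(200, {"applied": bool(applied)})


class StatusServer:
    """Background HTTP server bound to one engine."""

    def __init__(self, engine, port: int = 0, host: str = "127.0.0.1"):
        handler = type("BoundHandler", (_Handler,), {"engine": engine})
        self.httpd = ThreadingHTTPServer((host, port), handler)
        self.port = self.httpd.server_address[1]
        self._thread = threading.Thread(target=self.httpd.serve_forever, daemon=True)

    @property
    def url(self) -> str:
        return f"http://{self.httpd.server_address[0]}:{self.port}"

    def start(self) -> "StatusServer":
        self._thread.start()
        return self

    def stop(self) -> None:
        self.httpd.shutdown()
        self.httpd.server_close()


def serve_status(engine, port: int = 0) -> StatusServer:
    """Start the status/action endpoint for a running engine; returns the server."""
    return StatusServer(engine, port=port).start()
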