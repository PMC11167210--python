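"""Upload service and REST frontend.

:class:`DepletionService` owns the context store, the mapper index and the
background worker threads; it is the protocol's engine and is fully usable
in-process (tests drive it directly). :class:`start_http_server` wraps it in
a threaded stdlib HTTP server exposing the JSON protocol:

* ``POST /api/context`` -> ``{context_id, buffer_max, chunk_size_hint, mode}``
* ``POST /api/context/{id}/reads`` with ``{"reads": [{"id", "seq", "qual"}]}``
  -> 200 ``{occupancy, oversize_rejected}`` | 429 ``{retry_after}`` (plus a
  ``Retry-After`` header) | 404
* ``DELETE /api/context/{id}`` -> 200 close summary

Reads classified as host are never written to disk and never returned to any
client; on any worker failure the affected chunk's reads are counted as
discarded (the privacy-conservative direction).
"""

from __future__ import annotations

import json
import logging
import threading
import time
import uuid
from dataclasses import dataclass, field, asdict
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Optional

from . import buffering
from .buffering import (
    AdmissionDecision,
    ContextCounters,
    ContextStateError,
    ContextStore,
    UploadContext,
    admit_chunk,
    complete_chunk,
)
from .depletion import (
    DEFAULT_MAPQ_THRESHOLD,
    ConfigurationError,
    DepletionMode,
    Mapper,
    ReferenceSet,
    build_index,
    deplete_chunk,
)
from .sequence_io import Chunk, SequenceRead, write_fastq

logger = logging.getLogger(__name__)


class UnknownContextError(KeyError):
    pass


class BadPayloadError(ValueError):
    pass


@dataclass(frozen=True)
class Throttled:
    """Buffer full: the client should retry after ``retry_after`` seconds."""

    retry_after: float
    occupancy: int


@dataclass(frozen=True)
class Accepted:
    occupancy: int
    oversize_rejected: tuple = ()


@dataclass(frozen=True)
class ContextSummary:
    context_id: str
    received_reads: int
    retained_reads: int
    discarded_reads: int
    oversize_rejected_reads: int
    retained_ids: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retained_ids"] = list(self.retained_ids)
        return d


@dataclass
class ServerConfig:
    """All server tunables; every field has a CLI flag and config-file key."""

    mode: DepletionMode = DepletionMode.HOST_COMPETITIVE_RETENTION
    buffer_max: int = 100_000  # bases
    chunk_size_hint: int = 20_000  # bases; advisory for clients
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD
    worker_threads: int = 1
    host_fasta: Optional[str] = None
    pathogen_fasta: Optional[str] = None
    output_dir: Optional[str] = None
    persist_retained: bool = False
    return_ids: bool = True
    max_contexts: int = 64
    context_ttl: Optional[float] = None  # seconds; None disables GC
    retry_floor: float = buffering.DEFAULT_RETRY_FLOOR
    retry_cap: float = buffering.DEFAULT_RETRY_CAP
    rate_smoothing: float = buffering.DEFAULT_RATE_SMOOTHING
    mapper_backend: str = "seed"

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = DepletionMode(self.mode)
        if self.worker_threads < 1:
            raise ConfigurationError("worker_threads must be >= 1")
        if self.buffer_max < 1:
            raise ConfigurationError("buffer_max must be >= 1")
        if self.chunk_size_hint > self.buffer_max:
            logger.warning(
                "chunk_size_hint (%d) exceeds buffer_max (%d); clients using the "
                "hint will be throttled forever",
                self.chunk_size_hint,
                self.buffer_max,
            )
        if self.persist_retained and not self.output_dir:
            raise ConfigurationError("persist_retained requires output_dir")

    @classmethod
    def from_file(cls, path: str) -> "ServerConfig":
        """Parse a plain ``key = value`` configuration file."""
        kwargs: dict = {}
        bools = {"persist_retained", "return_ids"}
        ints = {
            "buffer_max", "chunk_size_hint", "mapq_threshold",
            "worker_threads", "max_contexts",
        }
        floats = {"context_ttl", "retry_floor", "retry_cap", "rate_smoothing"}
        with open(path, "rt", encoding="utf-8") as handle:
            for raw in handle:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key in bools:
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif key in ints:
                    kwargs[key] = int(value)
                elif key in floats:
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


class DepletionService:
    """Protocol engine: contexts, admission, background depletion workers."""

    def __init__(self, config: ServerConfig, mapper: Optional[Mapper] = None):
        self.config = config
        if mapper is None:
            refs = ReferenceSet.from_fasta(config.host_fasta, config.pathogen_fasta)
            mapper = build_index(refs, config.mode, backend=config.mapper_backend)
        self.mapper = mapper
        self.store = ContextStore(
            max_contexts=config.max_contexts, ttl=config.context_ttl
        )
        self._stop = threading.Event()
        self._work = threading.Event()
        self._threads: list = []

    # -- lifecycle ---------------------------------------------------------

    def start(self) -> "DepletionService":
        for i in range(self.config.worker_threads):
            t = threading.Thread(
                target=self._worker_loop, name=f"depletion-worker-{i}", daemon=True
            )
            t.start()
            self._threads.append(t)
        return self

    def stop(self) -> None:
        self._stop.set()
        self._work.set()
        for t in self._threads:
            t.join(timeout=5)
        self._threads.clear()

    def __enter__(self) -> "DepletionService":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    # -- protocol operations ----------------------------------------------

    def create_context(self, buffer_max: Optional[int] = None) -> dict:
        ctx = UploadContext(
            context_id=uuid.uuid4().hex,
            buffer_max=buffer_max or self.config.buffer_max,
            mode=self.config.mode,
            mapq_threshold=self.config.mapq_threshold,
        )
        self.store.expire_idle()
        self.store.create(ctx)
        logger.info("context %s created (buffer_max=%d)", ctx.context_id, ctx.buffer_max)
        return {
            "context_id": ctx.context_id,
            "buffer_max": ctx.buffer_max,
            "chunk_size_hint": self.config.chunk_size_hint,
            "mode": ctx.mode.value,
        }

    def submit_reads(self, context_id: str, payload: list):
        """Admit one chunk of reads; returns :class:`Accepted` or :class:`Throttled`.

        Individual reads longer than the context's buffer can never be
        buffered: the request succeeds but those reads are reported back as
        filtered (and counted), per the oversized-read rule. The whole
        request is otherwise all-or-nothing; a throttled request changes no
        state, so retrying it verbatim is safe.
        """
        ctx = self._get(context_id)
        reads = _parse_payload(payload)
        with ctx.lock:
            if ctx.state != "open":
                raise UnknownContextError(context_id)
            oversize = [r for r in reads if len(r) > ctx.buffer_max]
            rest = [r for r in reads if len(r) <= ctx.buffer_max]
            if rest:
                result = admit_chunk(
                    ctx,
                    Chunk(rest),
                    retry_floor=self.config.retry_floor,
                    retry_cap=self.config.retry_cap,
                )
                if result.decision is AdmissionDecision.REJECTED_FULL:
                    return Throttled(
                        retry_after=result.retry_after, occupancy=result.occupancy
                    )
            ctx.counters.received_reads += len(oversize)
            ctx.counters.oversize_rejected_reads += len(oversize)
            ctx.last_activity = time.monotonic()
            occupancy = ctx.occupancy
        if rest:
            self._work.set()
        return Accepted(
            occupancy=occupancy,
            oversize_rejected=tuple(r.read_id for r in oversize),
        )

    def close_context(self, context_id: str, timeout: float = 300.0) -> ContextSummary:
        """Drain the context's queue, persist retained reads, free its memory."""
        ctx = self._get(context_id)
        with ctx.condition:
            if ctx.state != "open":
                raise UnknownContextError(context_id)
            ctx.state = "closing"
            drained = ctx.condition.wait_for(lambda: ctx.idle, timeout=timeout)
            if not drained:
                raise TimeoutError(
                    f"context {context_id} did not drain within {timeout}s"
                )
            counters = ctx.counters
            retained_reads = list(ctx.retained_reads)
            retained_ids = tuple(ctx.retained_ids)
            ctx.retained_reads.clear()
            ctx.state = "closed"
        if self.config.persist_retained and retained_reads:
            out_dir = Path(self.config.output_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_fastq(retained_reads, out_dir / f"{context_id}.fastq")
        self.store.remove(context_id)
        logger.info(
            "context %s closed: received=%d retained=%d discarded=%d oversize=%d",
            context_id,
            counters.received_reads,
            counters.retained_reads,
            counters.discarded_reads,
            counters.oversize_rejected_reads,
        )
        return ContextSummary(
            context_id=context_id,
            received_reads=counters.received_reads,
            retained_reads=counters.retained_reads,
            discarded_reads=counters.discarded_reads,
            oversize_rejected_reads=counters.oversize_rejected_reads,
            retained_ids=retained_ids if self.config.return_ids else (),
        )

    # -- internals ---------------------------------------------------------

    def _get(self, context_id: str) -> UploadContext:
        ctx = self.store.get(context_id)
        if ctx is None:
            raise UnknownContextError(context_id)
        return ctx

    def _worker_loop(self) -> None:
        while not self._stop.is_set():
            item = self.store.dispatch_round_robin()
            if item is None:
                self._work.clear()
                self._work.wait(timeout=0.02)
                continue
            ctx, chunk = item
            started = time.monotonic()
            try:
                retained, discarded_ids = deplete_chunk(
                    self.mapper, chunk, ctx.mode, ctx.mapq_threshold
                )
            except Exception:
                logger.exception(
                    "mapper failure on context %s; discarding chunk of %d reads",
                    ctx.context_id,
                    len(chunk),
                )
                retained, discarded_ids = [], [r.read_id for r in chunk.reads]
            complete_chunk(
                ctx,
                chunk,
                retained,
                discarded_ids,
                elapsed=time.monotonic() - started,
                smoothing=self.config.rate_smoothing,
            )


def _parse_payload(payload) -> list:
    if not isinstance(payload, list) or not payload:
        raise BadPayloadError("'reads' must be a non-empty list")
    reads = []
    for i, item in enumerate(payload):
        if not isinstance(item, dict) or "id" not in item or "seq" not in item:
            raise BadPayloadError(f"read {i}: expected object with 'id' and 'seq'")
        try:
            reads.append(
                SequenceRead(
                    read_id=str(item["id"]),
                    bases=str(item["seq"]).upper(),
                    qualities=item.get("qual"),
                )
            )
        except ValueError as exc:
            raise BadPayloadError(f"read {i}: {exc}") from exc
    return reads


class _Handler(BaseHTTPRequestHandler):
    server_version = "streamdeplete"
    protocol_version = "HTTP/1.1"

    @property
    def service(self) -> DepletionService:
        return self.server.service  # type: ignore[attr-defined]

    def log_message(self, fmt, *args):  # route access logs through logging
        logger.debug("%s " + fmt, self.address_string(), *args)

    def _json(self, status: int, body: dict, headers: Optional[dict] = None) -> None:
        data = json.dumps(body).encode()
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(data)))
        for key, value in (headers or {}).items():
            self.send_header(key, value)
        self.end_headers()
        self.wfile.write(data)

    def _read_body(self) -> dict:
        length = int(self.headers.get("Content-Length", 0) or 0)
        if length == 0:
            return {}
        try:
            return json.loads(self.rfile.read(length))
        except json.JSONDecodeError as exc:
            raise BadPayloadError(f"invalid JSON body: {exc}") from exc

    def do_POST(self) -> None:  # noqa: N802 (stdlib naming)
        try:
            parts = self.path.strip("/").split("/")
            if parts == ["api", "context"]:
                body = self._read_body()
                self._json(201, self.service.create_context(body.get("buffer_max")))
            elif (
                len(parts) == 4
                and parts[:2] == ["api", "context"]
                and parts[3] == "reads"
            ):
                body = self._read_body()
                result = self.service.submit_reads(parts[2], body.get("reads"))
                if isinstance(result, Throttled):
                    self._json(
                        429,
                        {
                            "retry_after": result.retry_after,
                            "occupancy": result.occupancy,
                        },
                        headers={"Retry-After": str(result.retry_after)},
                    )
                else:
                    self._json(
                        200,
                        {
                            "occupancy": result.occupancy,
                            "oversize_rejected": list(result.oversize_rejected),
                        },
                    )
            else:
                self._json(404, {"error": "no such endpoint"})
        except UnknownContextError:
            self._json(404, {"error": "unknown context"})
        except BadPayloadError as exc:
            self._json(400, {"error": str(exc)})
        except ContextStateError as exc:
            self._json(503, {"error": str(exc)})
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("internal error")
            self._json(500, {"error": str(exc)})

    def do_DELETE(self) -> None:  # noqa: N802
        try:
            parts = self.path.strip("/").split("/")
            if len(parts) == 3 and parts[:2] == ["api", "context"]:
                summary = self.service.close_context(parts[2])
                self._json(200, summary.to_dict())
            else:
                self._json(404, {"error": "no such endpoint"})
        except UnknownContextError:
            self._json(404, {"error": "unknown context"})
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("internal error")
            self._json(500, {"error": str(exc)})


def start_http_server(
    service: DepletionService, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Serve the REST protocol in a daemon thread; caller owns shutdown()."""
    httpd = ThreadingHTTPServer((host, port), _Handler)
    httpd.service = service  # type: ignore[attr-defined]
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    return httpd
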