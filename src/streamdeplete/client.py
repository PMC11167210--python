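"""Uploader: stream a FASTQ file to a depletion server, honoring throttling.

One chunk is in flight at a time; a throttled chunk is resent only after the
server-advised wait (with a small seeded jitter to de-synchronize concurrent
clients). Exceeding ``max_retries`` on a single chunk aborts the transfer,
closing the context and returning the partial report.
"""

from __future__ import annotations

import json
import logging
import random
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Optional

from .sequence_io import Chunk, chunk_stream, read_fastq

logger = logging.getLogger(__name__)

DEFAULT_MAX_RETRIES = 50
JITTER_FRACTION = 0.2


class TransferError(RuntimeError):
    """Aborted transfer; carries the context id and the partial report."""

    def __init__(self, message: str, context_id: str, report: "TransferReport"):
        super().__init__(message)
        self.context_id = context_id
        self.report = report


@dataclass
class TransferReport:
    sent_reads: int = 0
    retained_reads: int = 0
    discarded_reads: int = 0
    oversize_rejected_reads: int = 0
    retries: int = 0
    elapsed: float = 0.0
    retained_ids: Optional[list] = None
    complete: bool = False

    @property
    def conserved(self) -> bool:
        return self.sent_reads == (
            self.retained_reads
            + self.discarded_reads
            + self.oversize_rejected_reads
        )


class HttpTransport:
    """Thin JSON-over-HTTP binding of the upload protocol."""

    def __init__(self, server_url: str, timeout: float = 30.0):
        self.base = server_url.rstrip("/")
        self.timeout = timeout

    def _request(self, method: str, path: str, body: Optional[dict] = None):
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(
            f"{self.base}{path}",
            data=data,
            method=method,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, json.loads(resp.read() or b"{}")
        except urllib.error.HTTPError as exc:
            return exc.code, json.loads(exc.read() or b"{}")

    def create_context(self, buffer_max: Optional[int] = None) -> dict:
        status, body = self._request(
            "POST", "/api/context", {"buffer_max": buffer_max} if buffer_max else {}
        )
        if status != 201:
            raise TransferError(
                f"context creation refused ({status}): {body.get('error')}",
                context_id="",
                report=TransferReport(),
            )
        return body

    def submit(self, context_id: str, chunk: Chunk) -> tuple:
        payload = {
            "reads": [
                {"id": r.read_id, "seq": r.bases, "qual": r.qualities}
                for r in chunk.reads
            ]
        }
        return self._request("POST", f"/api/context/{context_id}/reads", payload)

    def close(self, context_id: str) -> tuple:
        return self._request("DELETE", f"/api/context/{context_id}")


def upload_file(
    path,
    server_url: Optional[str] = None,
    chunk_size: Optional[int] = None,
    max_retries: int = DEFAULT_MAX_RETRIES,
    transport=None,
    sleep: Callable[[float], None] = time.sleep,
    jitter_seed: Optional[int] = None,
    clock: Callable[[], float] = time.monotonic,
) -> TransferReport:
    """Upload a FASTQ file (plain or gzip) and return the transfer report.

    ``transport`` may replace the HTTP binding (used for in-process tests);
    ``sleep`` and ``clock`` are injectable for deterministic throttling tests.
    """
    if transport is None:
        if server_url is None:
            raise ValueError("either server_url or transport is required")
        transport = HttpTransport(server_url)
    rng = random.Random(jitter_seed)
    started = clock()
    descriptor = transport.create_context()
    context_id = descriptor["context_id"]
    effective_chunk = chunk_size or descriptor.get("chunk_size_hint") or 20_000
    report = TransferReport()

    def close_and_fill() -> None:
        status, body = transport.close(context_id)
        if status == 200:
            report.retained_reads = body.get("retained_reads", 0)
            report.discarded_reads = body.get("discarded_reads", 0)
            report.oversize_rejected_reads = body.get("oversize_rejected_reads", 0)
            report.retained_ids = body.get("retained_ids")
        report.elapsed = clock() - started

    for chunk in chunk_stream(read_fastq(path), effective_chunk):
        attempts = 0
        while True:
            status, body = transport.submit(context_id, chunk)
            if status == 200:
                report.sent_reads += len(chunk)
                break
            if status == 429:
                attempts += 1
                report.retries += 1
                if attempts > max_retries:
                    close_and_fill()
                    raise TransferError(
                        f"chunk exceeded {max_retries} retries",
                        context_id=context_id,
                        report=report,
                    )
                advised = float(body.get("retry_after", 1.0))
                # additive jitter only: never resend before the advised wait
                sleep(advised * (1.0 + JITTER_FRACTION * rng.random()))
                continue
            close_and_fill()
            raise TransferError(
                f"server error {status}: {body.get('error')}",
                context_id=context_id,
                report=report,
            )
    close_and_fill()
    report.complete = report.conserved
    if not report.complete:
        logger.warning(
            "transfer of %s closed without conservation: sent=%d accounted=%d",
            path,
            report.sent_reads,
            report.retained_reads
            + report.discarded_reads
            + report.oversize_rejected_reads,
        )
    return report
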