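"""Bounded per-upload buffer with atomic admission control.

The buffer is the system's privacy guarantee: at no externally observable
instant does the un-depleted data held for one upload exceed ``buffer_max``
bases. Admission is all-or-nothing per chunk and the check-and-add is a
single atomic step under the context lock; occupancy is decremented when a
chunk is *dispatched* to the mapper (not when mapping completes), so the
depletion worker holds at most one chunk per thread outside the bound.

A throttled client is told how long to wait via a retry-after estimate
calibrated from an exponential moving average of the observed mapping rate.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
import threading
import time
from dataclasses import dataclass, field
from typing import Optional

from .depletion import DepletionMode
from .sequence_io import Chunk

logger = logging.getLogger(__name__)

DEFAULT_RETRY_FLOOR = 1.0  # seconds
DEFAULT_RETRY_CAP = 60.0  # seconds
DEFAULT_RATE_SMOOTHING = 0.3
DEFAULT_PRIOR_RATE = 100_000.0  # bases/second before any observation


class ContextStateError(RuntimeError):
    """Operation on a closed (or closing) upload context."""


class AdmissionDecision(str, enum.Enum):
    ACCEPTED = "accepted"
    REJECTED_FULL = "rejected_full"
    REJECTED_OVERSIZE = "rejected_oversize"


@dataclass(frozen=True)
class AdmissionResult:
    decision: AdmissionDecision
    occupancy: int
    retry_after: Optional[float] = None  # present iff rejected_full

    def __post_init__(self) -> None:
        if self.decision is AdmissionDecision.REJECTED_FULL:
            if self.retry_after is None or self.retry_after <= 0:
                raise ValueError("rejected_full requires retry_after > 0")


@dataclass
class RateEstimate:
    """EMA of the depletion throughput in bases/second."""

    bases_per_second: float = DEFAULT_PRIOR_RATE
    updated_at: float = 0.0
    observed: bool = False  # False until the first completed chunk


def compute_retry_after(
    needed: int,
    rate: RateEstimate,
    floor: float = DEFAULT_RETRY_FLOOR,
    cap: float = DEFAULT_RETRY_CAP,
) -> float:
    """Seconds until ``needed`` bases should have drained at the current rate."""
    if needed <= 0:
        raise ValueError(f"needed must be > 0, got {needed}")
    if rate.bases_per_second <= 0:
        return cap
    return min(cap, max(floor, math.ceil(needed / rate.bases_per_second)))


def update_rate(
    rate: RateEstimate,
    chunk_bases: int,
    elapsed: float,
    smoothing: float = DEFAULT_RATE_SMOOTHING,
    now: Optional[float] = None,
) -> RateEstimate:
    """Fold one completed chunk into the rate EMA.

    The first observation replaces the configured prior entirely;
    non-positive elapsed times are discarded (and logged).
    """
    if not 0 < smoothing <= 1:
        raise ValueError(f"smoothing must be in (0, 1], got {smoothing}")
    if elapsed <= 0:
        logger.warning("discarding rate observation with elapsed=%s", elapsed)
        return rate
    observation = chunk_bases / elapsed
    new_rate = (
        observation
        if not rate.observed
        else smoothing * observation + (1 - smoothing) * rate.bases_per_second
    )
    return RateEstimate(
        bases_per_second=new_rate,
        updated_at=time.monotonic() if now is None else now,
        observed=True,
    )


@dataclass
class ContextCounters:
    received_reads: int = 0
    retained_reads: int = 0
    discarded_reads: int = 0
    oversize_rejected_reads: int = 0


@dataclass
class UploadContext:
    """Server-side state of one upload session.

    All mutation happens under ``lock``; ``condition`` (on the same lock)
    signals chunk completions so that close can wait for the queue to drain.
    """

    context_id: str
    buffer_max: int
    mode: DepletionMode
    mapq_threshold: int = 20
    occupancy: int = 0
    in_flight_chunks: int = 0
    queued_chunks: list = field(default_factory=list)
    counters: ContextCounters = field(default_factory=ContextCounters)
    retained_ids: list = field(default_factory=list)
    retained_reads: list = field(default_factory=list)
    state: str = "open"  # open | closing | closed
    rate: RateEstimate = field(default_factory=RateEstimate)
    created_at: float = field(default_factory=time.monotonic)
    last_activity: float = field(default_factory=time.monotonic)
    lock: threading.RLock = field(default_factory=threading.RLock, repr=False)
    condition: threading.Condition = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.buffer_max < 1:
            raise ValueError(f"buffer_max must be >= 1, got {self.buffer_max}")
        self.condition = threading.Condition(self.lock)

    @property
    def idle(self) -> bool:
        return not self.queued_chunks and self.in_flight_chunks == 0


def admit_chunk(
    ctx: UploadContext,
    chunk: Chunk,
    retry_floor: float = DEFAULT_RETRY_FLOOR,
    retry_cap: float = DEFAULT_RETRY_CAP,
) -> AdmissionResult:
    """Atomically admit a chunk, reject it as full, or reject an oversized read.

    A singleton chunk whose one read exceeds ``buffer_max`` can never be
    admitted; it is rejected immediately and its read counted as filtered
    without entering the buffer.
    """
    with ctx.lock:
        if ctx.state != "open":
            raise ContextStateError(f"context {ctx.context_id} is {ctx.state}")
        ctx.last_activity = time.monotonic()
        if len(chunk) == 1 and chunk.total_bases > ctx.buffer_max:
            ctx.counters.received_reads += 1
            ctx.counters.oversize_rejected_reads += 1
            return AdmissionResult(
                decision=AdmissionDecision.REJECTED_OVERSIZE,
                occupancy=ctx.occupancy,
            )
        if ctx.occupancy + chunk.total_bases > ctx.buffer_max:
            needed = ctx.occupancy + chunk.total_bases - ctx.buffer_max
            return AdmissionResult(
                decision=AdmissionDecision.REJECTED_FULL,
                occupancy=ctx.occupancy,
                retry_after=compute_retry_after(
                    needed, ctx.rate, retry_floor, retry_cap
                ),
            )
        ctx.occupancy += chunk.total_bases
        ctx.queued_chunks.append(chunk)
        ctx.counters.received_reads += len(chunk)
        return AdmissionResult(
            decision=AdmissionDecision.ACCEPTED, occupancy=ctx.occupancy
        )


def dispatch_next(ctx: UploadContext) -> Optional[Chunk]:
    """Pop the oldest queued chunk for depletion, freeing its buffer space now."""
    with ctx.lock:
        if not ctx.queued_chunks:
            return None
        chunk = ctx.queued_chunks.pop(0)
        ctx.occupancy -= chunk.total_bases
        ctx.in_flight_chunks += 1
        return chunk


def complete_chunk(
    ctx: UploadContext,
    chunk: Chunk,
    retained: list,
    discarded_ids: list,
    elapsed: Optional[float] = None,
    smoothing: float = DEFAULT_RATE_SMOOTHING,
) -> None:
    """Record the depletion outcome of a dispatched chunk."""
    with ctx.lock:
        ctx.in_flight_chunks -= 1
        ctx.counters.retained_reads += len(retained)
        ctx.counters.discarded_reads += len(discarded_ids)
        ctx.retained_reads.extend(retained)
        ctx.retained_ids.extend(r.read_id for r in retained)
        if elapsed is not None and elapsed > 0:
            ctx.rate = update_rate(ctx.rate, chunk.total_bases, elapsed, smoothing)
        ctx.condition.notify_all()


class ContextStore:
    """Thread-safe in-process registry of open upload contexts.

    Contract for any backend: atomic check-and-increment of occupancy, FIFO
    chunk order per context, fair (round-robin) dispatch across contexts.
    Contexts idle beyond ``ttl`` seconds may be purged by ``expire_idle``.
    """

    def __init__(self, max_contexts: int = 64, ttl: Optional[float] = None):
        self.max_contexts = max_contexts
        self.ttl = ttl
        self._contexts: dict = {}
        self._lock = threading.RLock()
        self._rr = itertools.count()
        self._id_counter = itertools.count(1)

    def create(self, ctx: UploadContext) -> None:
        with self._lock:
            if len(self._contexts) >= self.max_contexts:
                raise ContextStateError(
                    f"server at maximum of {self.max_contexts} concurrent contexts"
                )
            self._contexts[ctx.context_id] = ctx

    def get(self, context_id: str) -> Optional[UploadContext]:
        with self._lock:
            return self._contexts.get(context_id)

    def remove(self, context_id: str) -> None:
        with self._lock:
            self._contexts.pop(context_id, None)

    def open_contexts(self) -> list:
        with self._lock:
            return list(self._contexts.values())

    def dispatch_round_robin(self) -> Optional[tuple]:
        """Pop one queued chunk from the next context that has work."""
        with self._lock:
            contexts = list(self._contexts.values())
        if not contexts:
            return None
        start = next(self._rr) % len(contexts)
        for i in range(len(contexts)):
            ctx = contexts[(start + i) % len(contexts)]
            chunk = dispatch_next(ctx)
            if chunk is not None:
                return ctx, chunk
        return None

    def expire_idle(self, now: Optional[float] = None) -> list:
        """Close and purge contexts idle beyond the TTL; returns their IDs."""
        if self.ttl is None:
            return []
        now = time.monotonic() if now is None else now
        expired = []
        with self._lock:
            for context_id, ctx in list(self._contexts.items()):
                with ctx.lock:
                    stale = (
                        now - ctx.last_activity > self.ttl
                        and ctx.idle
                        and ctx.state == "open"
                    )
                    if stale:
                        ctx.state = "closed"
                        del self._contexts[context_id]
                        expired.append(context_id)
        if expired:
            logger.info("expired idle contexts: %s", expired)
        return expired
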