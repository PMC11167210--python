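"""SNP-coverage re-identifiability model for buffer sizing.

The worst case for a bounded transfer buffer is that every buffered base is
human. The privacy proxy is the number of genotyping-array positions covered
by a buffer's worth of reads placed uniformly at random on the genome:

    E[covered] = S * (1 - (1 - L/G)^n)

with panel size ``S``, genome length ``G``, read length ``L`` and
``n = floor(B/L)`` reads filling a buffer of ``B`` bases (the trimmed last
read of length ``r = B - nL`` contributes one further factor ``1 - r/G``).
Each panel site is covered by one uniform read of length L with probability
L/G (edge effects of order L/G ignored), independently across reads, so the
count is Binomial(S, p) with p the per-site coverage probability. For
``B << G`` the expectation approximates ``S*B/G``: one covered SNP per
``G/S`` buffered bases.

A Monte-Carlo simulator mirrors the empirical design — draw reads until
their cumulative length equals the buffer size, trim the last — and a
buffer-size advisor inverts the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .sequence_io import SnpPanel

#: Human-scale defaults: a ~2.37M-site population genotyping array on a
#: ~3.1 Gb genome (implementation constants for the human-like presets).
HUMAN_PANEL_SIZE = 2_372_000
HUMAN_GENOME_LENGTH = 3_100_000_000


@dataclass(frozen=True)
class RiskModelParams:
    """Closed-form model inputs; ``n_reads`` derives from B and L."""

    panel_size: int  # S
    genome_length: int  # G
    read_length: int  # L (expected length when lengths vary)
    buffer_size: int  # B

    def __post_init__(self) -> None:
        if self.panel_size < 0:
            raise ValueError("panel_size must be >= 0")
        if not 1 <= self.read_length <= self.genome_length:
            raise ValueError("need 1 <= read_length <= genome_length")
        if self.panel_size > self.genome_length:
            raise ValueError("panel_size cannot exceed genome_length")
        if self.buffer_size < 0:
            raise ValueError("buffer_size must be >= 0")

    @property
    def n_reads(self) -> int:
        return self.buffer_size // self.read_length


@dataclass(frozen=True)
class RiskSimResult:
    """Covered-SNP counts across simulation replicates."""

    replicate_counts: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", float(np.mean(self.replicate_counts)))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.replicate_counts, q))

    def fraction_at_most(self, threshold: float) -> float:
        return float(np.mean(self.replicate_counts <= threshold))


def expected_snps_covered(params: RiskModelParams) -> float:
    """Expected number of panel positions covered by a full buffer of reads."""
    S, G, L, B = (
        params.panel_size,
        params.genome_length,
        params.read_length,
        params.buffer_size,
    )
    if S == 0 or B == 0:
        return 0.0
    n, r = divmod(B, L)
    miss = (1.0 - L / G) ** n
    if r:
        miss *= 1.0 - r / G
    return S * (1.0 - miss)


ReadLengthSource = Union[int, Callable[[np.random.Generator], int]]


def _panel_positions(
    panel: Union[SnpPanel, Sequence[int], int, float],
    genome_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Normalize a panel spec to sorted 0-based positions.

    Accepts an explicit :class:`SnpPanel` (single-sequence coordinate space),
    a position sequence, an integer site count, or a density in (0, 1).
    """
    if isinstance(panel, SnpPanel):
        positions = np.array([p - 1 for _, p in panel.entries], dtype=np.int64)
    elif isinstance(panel, float):
        n_sites = int(round(panel * genome_length))
        positions = _distinct_uniform(n_sites, genome_length, rng)
    elif isinstance(panel, int):
        positions = _distinct_uniform(panel, genome_length, rng)
    else:
        positions = np.asarray(panel, dtype=np.int64)
    positions = np.unique(positions)
    if positions.size and (positions[0] < 0 or positions[-1] >= genome_length):
        raise ValueError("panel positions outside the genome")
    return positions


def _distinct_uniform(n: int, genome_length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct uniform 0-based positions; rejection-samples collisions."""
    if n > genome_length:
        raise ValueError("more panel sites than genome positions")
    positions = np.unique(rng.integers(0, genome_length, size=n))
    while positions.size < n:
        extra = rng.integers(0, genome_length, size=n - positions.size)
        positions = np.unique(np.concatenate([positions, extra]))
    return positions


def simulate_buffer_coverage(
    genome_length: int,
    panel: Union[SnpPanel, Sequence[int], int, float],
    read_length_source: ReadLengthSource,
    buffer_size: int,
    replicates: int = 10,
    seed: Optional[int] = None,
) -> RiskSimResult:
    """Monte-Carlo worst-case coverage: fill the buffer with random reads.

    Per replicate, reads (uniform start, entirely on the genome; lengths from
    ``read_length_source``) are drawn until their cumulative length equals
    ``buffer_size``, trimming the last read, and the distinct panel positions
    under the placed intervals are counted. Positions-only: no sequence data
    is touched, so human-genome-scale parameters run in milliseconds.
    """
    if buffer_size < 0:
        raise ValueError("buffer_size must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    positions = _panel_positions(panel, genome_length, rng)
    counts = np.zeros(replicates, dtype=np.int64)
    for rep in range(replicates):
        covered: set = set()
        remaining = buffer_size
        while remaining > 0:
            length = (
                read_length_source
                if isinstance(read_length_source, int)
                else int(read_length_source(rng))
            )
            length = max(1, min(length, genome_length))
            if length > remaining:  # trim the last read to fill exactly
                length = remaining
            start = int(rng.integers(0, genome_length - length + 1))
            lo = int(np.searchsorted(positions, start, side="left"))
            hi = int(np.searchsorted(positions, start + length, side="left"))
            covered.update(range(lo, hi))
            remaining -= length
        counts[rep] = len(covered)
    return RiskSimResult(replicate_counts=counts)


def lognormal_read_lengths(
    median: float, sigma: float = 0.6, minimum: int = 100
) -> Callable[[np.random.Generator], int]:
    """Long-read length sampler: log-normal with the given median."""
    mu = float(np.log(median))

    def sample(rng: np.random.Generator) -> int:
        return max(minimum, int(rng.lognormal(mean=mu, sigma=sigma)))

    return sample


@dataclass(frozen=True)
class BufferAdvice:
    buffer_size: int
    expected_snps: float
    capped: bool  # True when every size up to the cap meets the target


def advise_buffer_size(
    panel_size: int,
    genome_length: int,
    read_length: int,
    max_expected_snps: float,
    cap: int = 10_000_000_000,
) -> BufferAdvice:
    """Largest buffer (bases) whose expected covered-SNP count stays at or
    below ``max_expected_snps``.

    The expectation is non-decreasing in the buffer size, so a geometric
    scan followed by bisection to 1-base resolution is exact. When even the
    cap meets the target (e.g. the target is >= the panel size), the cap is
    returned with ``capped=True``.
    """
    if max_expected_snps <= 0:
        raise ValueError("max_expected_snps must be > 0")

    def expectation(B: int) -> float:
        return expected_snps_covered(
            RiskModelParams(panel_size, genome_length, read_length, B)
        )

    if expectation(cap) <= max_expected_snps:
        return BufferAdvice(buffer_size=cap, expected_snps=expectation(cap), capped=True)
    lo, hi = 0, 1  # invariant: expectation(lo) <= target < expectation(hi)
    while expectation(hi) <= max_expected_snps:
        lo, hi = hi, min(cap, hi * 2)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expectation(mid) <= max_expected_snps:
            lo = mid
        else:
            hi = mid
    return BufferAdvice(buffer_size=lo, expected_snps=expectation(lo), capped=False)
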