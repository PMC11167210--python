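"""Synthetic genomes, reads, SNP panels and contaminated mixtures.

Everything here is a pure function of its seed, so fixtures are regenerated
identically at test time instead of being shipped. The generators emulate
the shape of a clinical metagenomic transfer — a mostly-pathogen read set
carrying a small human contaminant fraction — at desk scale: default
genomes of 1 Mb (host stand-in) and 100 kb (pathogen), datasets of
10^3–10^4 reads. The error model is substitution-only (no indels), which
keeps the bundled exact-seed test mapper applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .depletion import reverse_complement
from .sequence_io import SequenceRead, SnpPanel

_BASES = np.array(list("ACGT"))
DEFAULT_HOST_GENOME_LENGTH = 1_000_000
DEFAULT_PATHOGEN_GENOME_LENGTH = 100_000
MAX_HOMOPOLYMER_RUN = 20


@dataclass(frozen=True)
class ReadProfile:
    """Read-length model: fixed-length short reads or log-normal long reads."""

    kind: str = "short"  # "short" | "long"
    length: int = 150  # fixed length for short reads
    median_length: int = 2_000  # long-read log-normal median
    sigma: float = 0.6
    min_length: int = 100

    def sample_lengths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "short":
            return np.full(n, self.length, dtype=np.int64)
        if self.kind == "long":
            lengths = rng.lognormal(np.log(self.median_length), self.sigma, size=n)
            return np.maximum(self.min_length, lengths.astype(np.int64))
        raise ValueError(f"unknown read profile kind {self.kind!r}")


@dataclass(frozen=True)
class SimulatedDatasetSpec:
    """Conditions for one contaminated dataset (counts, mixture, noise)."""

    n_reads: int = 10_000
    human_fraction: float = 0.01
    read_profile: ReadProfile = field(default_factory=ReadProfile)
    host_genome_length: int = DEFAULT_HOST_GENOME_LENGTH
    pathogen_genome_length: int = DEFAULT_PATHOGEN_GENOME_LENGTH
    error_rate: float = 0.005  # per-base substitution probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.human_fraction <= 1.0:
            raise ValueError("human_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass(frozen=True)
class ReadOrigin:
    """Truth record for one simulated read."""

    read_id: str
    source: str  # genome name
    start: int  # 1-based leftmost position on the source
    length: int
    strand: str  # "+" | "-"
    substitutions: int


def generate_genome(
    length: int, seed: int, gc: float = 0.5, name: str = "synthetic"
) -> tuple:
    """Reproducible random genome with a target GC content.

    Homopolymer runs are capped at 20 bases (a long run would let reads map
    to many positions at once, which defeats seed-based test mappers).
    Returns ``(name, sequence)``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    # break homopolymer runs deterministically
    run = 1
    for i in range(1, length):
        if codes[i] == codes[i - 1]:
            run += 1
            if run > MAX_HOMOPOLYMER_RUN:
                codes[i] = (codes[i] + 1 + int(rng.integers(0, 3))) % 4
                run = 1
        else:
            run = 1
    return name, "".join(_BASES[codes])


def sample_reads(
    genome: tuple,
    n: int,
    read_profile: ReadProfile,
    error_rate: float,
    seed: int,
    id_prefix: Optional[str] = None,
) -> tuple:
    """Sample reads uniformly from a genome; returns (reads, truth origins).

    Starts are uniform over placements that fit entirely on the genome;
    strands are random; substitution errors are Bernoulli(error_rate) per
    base. Qualities are a constant placeholder (the pipeline never filters
    on quality).
    """
    name, sequence = genome
    rng = np.random.default_rng(seed)
    prefix = id_prefix or name
    lengths = np.minimum(read_profile.sample_lengths(n, rng), len(sequence))
    reads: list = []
    origins: list = []
    for i in range(n):
        length = int(lengths[i])
        start = int(rng.integers(0, len(sequence) - length + 1))
        fragment = sequence[start : start + length]
        n_subs = int(rng.binomial(length, error_rate)) if error_rate > 0 else 0
        if n_subs:
            chars = list(fragment)
            for pos in rng.choice(length, size=n_subs, replace=False):
                original = chars[pos]
                choices = [b for b in "ACGT" if b != original]
                chars[pos] = choices[int(rng.integers(0, 3))]
            fragment = "".join(chars)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        read_id = f"{prefix}_read_{i}"
        reads.append(
            SequenceRead(read_id=read_id, bases=fragment, qualities="I" * length)
        )
        origins.append(
            ReadOrigin(
                read_id=read_id,
                source=name,
                start=start + 1,
                length=length,
                strand=strand,
                substitutions=n_subs,
            )
        )
    return reads, origins


def generate_contaminated_dataset(
    spec: SimulatedDatasetSpec,
    host_genome: Optional[tuple] = None,
    pathogen_genome: Optional[tuple] = None,
) -> tuple:
    """Mixture dataset: exactly round(n_reads * human_fraction) host reads.

    Returns ``(reads, labels)`` where ``labels`` maps read_id to ``"host"``
    or ``"pathogen"`` (an exact partition of the dataset). Reads are
    shuffled with the spec seed so host reads are interleaved, as in a real
    contaminated sample.
    """
    if host_genome is None:
        host_genome = generate_genome(
            spec.host_genome_length, seed=spec.seed * 7 + 1, name="host_chr1"
        )
    if pathogen_genome is None:
        pathogen_genome = generate_genome(
            spec.pathogen_genome_length, seed=spec.seed * 7 + 2, name="pathogen_chr1"
        )
    n_host = int(round(spec.n_reads * spec.human_fraction))
    n_pathogen = spec.n_reads - n_host
    host_reads, _ = sample_reads(
        host_genome,
        n_host,
        spec.read_profile,
        spec.error_rate,
        seed=spec.seed * 7 + 3,
        id_prefix="host",
    )
    pathogen_reads, _ = sample_reads(
        pathogen_genome,
        n_pathogen,
        spec.read_profile,
        spec.error_rate,
        seed=spec.seed * 7 + 4,
        id_prefix="pathogen",
    )
    labels = {r.read_id: "host" for r in host_reads}
    labels.update({r.read_id: "pathogen" for r in pathogen_reads})
    reads = host_reads + pathogen_reads
    order = np.random.default_rng(spec.seed * 7 + 5).permutation(len(reads))
    return [reads[i] for i in order], labels


def generate_snp_panel(
    genome_length: int,
    n_snps: int,
    seed: int,
    sequence_name: str = "host_chr1",
) -> SnpPanel:
    """n distinct uniform 1-based panel positions, sorted; seed-reproducible."""
    if n_snps > genome_length:
        raise ValueError("n_snps cannot exceed genome_length")
    rng = np.random.default_rng(seed)
    positions = np.unique(rng.integers(1, genome_length + 1, size=n_snps))
    while positions.size < n_snps:
        extra = rng.integers(1, genome_length + 1, size=n_snps - positions.size)
        positions = np.unique(np.concatenate([positions, extra]))
    return SnpPanel(
        entries=tuple((sequence_name, int(p)) for p in positions)
    )


def dataset_with_references(spec: SimulatedDatasetSpec) -> tuple:
    """Contaminated dataset plus the genomes it was sampled from.

    Returns ``(reads, labels, host_genome, pathogen_genome)`` — the genome
    pair is exactly what a server must index to deplete this dataset.
    """
    host_genome = generate_genome(
        spec.host_genome_length, seed=spec.seed * 7 + 1, name="host_chr1"
    )
    pathogen_genome = generate_genome(
        spec.pathogen_genome_length, seed=spec.seed * 7 + 2, name="pathogen_chr1"
    )
    reads, labels = generate_contaminated_dataset(spec, host_genome, pathogen_genome)
    return reads, labels, host_genome, pathogen_genome


def long_read_spec(spec: SimulatedDatasetSpec, median_length: int = 2_000):
    """Convenience: the same dataset conditions with a long-read profile."""
    return replace(
        spec, read_profile=ReadProfile(kind="long", median_length=median_length)
    )
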