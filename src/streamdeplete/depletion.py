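"""Read classification for host depletion.

Reads are mapped against the mode-dependent reference set and each read's
*primary* (best) alignment decides retention:

* ``host_subtraction`` — map against the host genome only; discard reads
  that align to it confidently, keep everything else.
* ``simple_pathogen_retention`` — map against the target pathogen genome
  only; keep only reads that align to it confidently.
* ``host_competitive_retention`` — map against host + pathogen jointly;
  keep a read only when its primary alignment is to a pathogen sequence.

"Confidently" means mapping quality >= a threshold (default 20); a mapped
read below the threshold is treated as unaligned in every mode. Score ties
between a host and a pathogen placement resolve to host, the
privacy-conservative direction (the read is discarded in retention modes).

Two mapper backends implement one interface: :class:`SeedMatchMapper`, a
dependency-free exact-k-mer seed mapper suitable for synthetic data, and
:class:`Minimap2Mapper`, which shells out to the ``minimap2`` executable.
"""

from __future__ import annotations

import enum
import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .sequence_io import Chunk, SequenceRead, read_fasta

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_THRESHOLD = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DepletionMode(str, enum.Enum):
    HOST_SUBTRACTION = "host_subtraction"
    SIMPLE_PATHOGEN_RETENTION = "simple_pathogen_retention"
    HOST_COMPETITIVE_RETENTION = "host_competitive_retention"


class TargetClass(str, enum.Enum):
    HOST = "host"
    PATHOGEN = "pathogen"
    NONE = "none"


class Decision(str, enum.Enum):
    RETAIN = "retain"
    DISCARD = "discard"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentSummary:
    """Primary-alignment facts for one read."""

    read_id: str
    mapped: bool
    target_class: TargetClass = TargetClass.NONE
    mapq: Optional[int] = None
    is_primary: bool = True
    target_name: str = ""
    target_pos: int = 0  # 1-based alignment start

    def __post_init__(self) -> None:
        if not self.mapped and self.target_class is not TargetClass.NONE:
            raise ValueError("unmapped read cannot carry a target class")
        if self.mapped and self.mapq is None:
            raise ValueError("mapped read must carry a mapq")


@dataclass(frozen=True)
class ReferenceSet:
    """Named host and pathogen sequences; names are unique across classes."""

    host_sequences: dict
    pathogen_sequences: dict

    def __post_init__(self) -> None:
        overlap = set(self.host_sequences) & set(self.pathogen_sequences)
        if overlap:
            raise ConfigurationError(
                f"sequence names in both classes: {sorted(overlap)}"
            )

    @classmethod
    def from_fasta(
        cls,
        host_fasta: Optional[str] = None,
        pathogen_fasta: Optional[str] = None,
    ) -> "ReferenceSet":
        return cls(
            host_sequences=read_fasta(host_fasta) if host_fasta else {},
            pathogen_sequences=read_fasta(pathogen_fasta) if pathogen_fasta else {},
        )

    def class_of(self, target_name: str) -> TargetClass:
        if target_name in self.host_sequences:
            return TargetClass.HOST
        if target_name in self.pathogen_sequences:
            return TargetClass.PATHOGEN
        raise KeyError(target_name)

    def for_mode(self, mode: DepletionMode) -> dict:
        """Sequences indexed under the given mode ({name: (class, seq)})."""
        out = {}
        if mode in (
            DepletionMode.HOST_SUBTRACTION,
            DepletionMode.HOST_COMPETITIVE_RETENTION,
        ):
            out.update(
                {n: (TargetClass.HOST, s) for n, s in self.host_sequences.items()}
            )
        if mode in (
            DepletionMode.SIMPLE_PATHOGEN_RETENTION,
            DepletionMode.HOST_COMPETITIVE_RETENTION,
        ):
            out.update(
                {
                    n: (TargetClass.PATHOGEN, s)
                    for n, s in self.pathogen_sequences.items()
                }
            )
        return out


def _require_sequences(refs: ReferenceSet, mode: DepletionMode) -> None:
    need_host = mode in (
        DepletionMode.HOST_SUBTRACTION,
        DepletionMode.HOST_COMPETITIVE_RETENTION,
    )
    need_pathogen = mode in (
        DepletionMode.SIMPLE_PATHOGEN_RETENTION,
        DepletionMode.HOST_COMPETITIVE_RETENTION,
    )
    if need_host and not refs.host_sequences:
        raise ConfigurationError(f"mode {mode.value} requires a host reference")
    if need_pathogen and not refs.pathogen_sequences:
        raise ConfigurationError(f"mode {mode.value} requires a pathogen reference")


class Mapper:
    """Maps reads to the configured reference set; subclasses implement map_chunk."""

    def map_read(self, read: SequenceRead) -> AlignmentSummary:
        return self.map_chunk([read])[0]

    def map_chunk(
        self, reads: Sequence[SequenceRead]
    ) -> Sequence[AlignmentSummary]:
        raise NotImplementedError


class SeedMatchMapper(Mapper):
    """Exact-k-mer seed mapper with diagonal voting.

    Every k-mer of each indexed sequence is stored; a read votes for
    (sequence, diagonal) pairs with its own k-mers on both strands, and the
    best-supported diagonal becomes the primary alignment. Mapping quality
    scales with the margin between the best and second-best locations:
    a unique location gets MAPQ 60, an exact tie 0. Host/pathogen ties
    resolve to host. Suitable for substitution-only synthetic reads; no
    indel tolerance.
    """

    def __init__(
        self,
        refs: ReferenceSet,
        mode: DepletionMode,
        k: int = 21,
        stride: int = 3,
        min_seed_hits: int = 2,
    ):
        _require_sequences(refs, mode)
        self.refs = refs
        self.mode = mode
        self.k = k
        self.stride = stride
        self.min_seed_hits = min_seed_hits
        self._class_of: dict = {}
        self._index: dict = {}
        for name, (target_class, seq) in refs.for_mode(mode).items():
            self._class_of[name] = target_class
            for pos in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def map_chunk(
        self, reads: Sequence[SequenceRead]
    ) -> Sequence[AlignmentSummary]:
        return [self._map_one(read) for read in reads]

    def _map_one(self, read: SequenceRead) -> AlignmentSummary:
        votes: dict = {}
        for strand, seq in (("+", read.bases), ("-", reverse_complement(read.bases))):
            for off in range(0, max(1, len(seq) - self.k + 1), self.stride):
                for name, pos in self._index.get(seq[off : off + self.k], ()):
                    key = (name, strand, pos - off)
                    votes[key] = votes.get(key, 0) + 1
        if not votes:
            return AlignmentSummary(read_id=read.read_id, mapped=False)
        # Deterministic order: host outranks pathogen on equal support.
        ranked = sorted(
            votes.items(),
            key=lambda item: (
                -item[1],
                0 if self._class_of[item[0][0]] is TargetClass.HOST else 1,
                item[0],
            ),
        )
        (name, _strand, diag), best = ranked[0]
        if best < self.min_seed_hits:
            return AlignmentSummary(read_id=read.read_id, mapped=False)
        second = ranked[1][1] if len(ranked) > 1 else 0
        mapq = 60 if second == 0 else min(60, int(60 * (best - second) / best))
        return AlignmentSummary(
            read_id=read.read_id,
            mapped=True,
            target_class=self._class_of[name],
            mapq=mapq,
            is_primary=True,
            target_name=name,
            target_pos=max(1, diag + 1),
        )


class Minimap2Mapper(Mapper):
    """Adapter over the ``minimap2`` executable (SAM output parsed via pysam).

    Reads are mapped in batches per chunk; only primary alignments are kept.
    """

    def __init__(
        self,
        refs: ReferenceSet,
        mode: DepletionMode,
        preset: str = "sr",
        executable: str = "minimap2",
    ):
        _require_sequences(refs, mode)
        self.refs = refs
        self.mode = mode
        self.preset = preset
        self.executable = executable
        self._class_of = {
            name: target_class
            for name, (target_class, _) in refs.for_mode(mode).items()
        }
        self._ref_dir = tempfile.TemporaryDirectory(prefix="streamdeplete-ref-")
        self._ref_path = Path(self._ref_dir.name) / "reference.fa"
        with open(self._ref_path, "w", encoding="ascii") as handle:
            for name, (_, seq) in refs.for_mode(mode).items():
                handle.write(f">{name}\n{seq}\n")

    def map_chunk(
        self, reads: Sequence[SequenceRead]
    ) -> Sequence[AlignmentSummary]:
        import pysam

        from .sequence_io import write_fastq

        with tempfile.TemporaryDirectory(prefix="streamdeplete-map-") as tmp:
            reads_path = Path(tmp) / "reads.fastq"
            with open(reads_path, "wb") as handle:
                write_fastq(reads, handle)
            sam_path = Path(tmp) / "out.sam"
            cmd = [
                self.executable,
                "-a",
                "-x",
                self.preset,
                "--secondary=no",
                "-o",
                str(sam_path),
                str(self._ref_path),
                str(reads_path),
            ]
            subprocess.run(
                cmd, check=True, stdout=subprocess.DEVNULL, stderr=subprocess.DEVNULL
            )
            best: dict = {}
            with pysam.AlignmentFile(str(sam_path), "r") as sam:
                for aln in sam:
                    if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                        continue
                    best[aln.query_name] = AlignmentSummary(
                        read_id=aln.query_name,
                        mapped=True,
                        target_class=self._class_of[aln.reference_name],
                        mapq=aln.mapping_quality,
                        is_primary=True,
                        target_name=aln.reference_name,
                        target_pos=aln.reference_start + 1,
                    )
        return [
            best.get(r.read_id, AlignmentSummary(read_id=r.read_id, mapped=False))
            for r in reads
        ]


def build_index(
    refs: ReferenceSet,
    mode: DepletionMode,
    backend: str = "seed",
    **kwargs,
) -> Mapper:
    """Build the mode-appropriate mapper index (``seed`` or ``minimap2``)."""
    if backend == "seed":
        return SeedMatchMapper(refs, mode, **kwargs)
    if backend == "minimap2":
        return Minimap2Mapper(refs, mode, **kwargs)
    raise ConfigurationError(f"unknown mapper backend {backend!r}")


def classify_read(
    aln: AlignmentSummary,
    mode: DepletionMode,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> Decision:
    """Retain-or-discard decision for one read's primary alignment.

    A read mapped with MAPQ below the threshold counts as unaligned:
    retained under host subtraction, discarded under both retention modes.
    """
    if not isinstance(mode, DepletionMode):
        raise ConfigurationError(f"unknown depletion mode {mode!r}")
    confident = (
        aln.mapped and aln.is_primary and aln.mapq is not None
        and aln.mapq >= mapq_threshold
    )
    if mode is DepletionMode.HOST_SUBTRACTION:
        if confident and aln.target_class is TargetClass.HOST:
            return Decision.DISCARD
        return Decision.RETAIN
    if mode in (
        DepletionMode.SIMPLE_PATHOGEN_RETENTION,
        DepletionMode.HOST_COMPETITIVE_RETENTION,
    ):
        if confident and aln.target_class is TargetClass.PATHOGEN:
            return Decision.RETAIN
        return Decision.DISCARD
    raise ConfigurationError(f"unknown depletion mode {mode!r}")


def deplete_chunk(
    mapper: Mapper,
    chunk: Chunk,
    mode: DepletionMode,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
) -> tuple:
    """Partition a chunk into (retained reads, discarded read IDs).

    The partition is exhaustive and disjoint; discarded read *content* is
    dropped here and never persisted.
    """
    retained: list = []
    discarded_ids: list = []
    for read, aln in zip(chunk.reads, mapper.map_chunk(chunk.reads)):
        if classify_read(aln, mode, mapq_threshold) is Decision.RETAIN:
            retained.append(read)
        else:
            discarded_ids.append(read.read_id)
    return retained, discarded_ids
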