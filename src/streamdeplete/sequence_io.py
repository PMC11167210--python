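"""Sequencing read I/O and chunking.

FASTQ records are streamed lazily so that arbitrarily large files can be
uploaded without ever being held in memory; the transfer protocol's unit of
accounting is the *base*, so chunking packs reads greedily up to a base
budget and never splits a read across chunks.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """Malformed FASTQ input; carries the byte offset and 0-based record index."""

    def __init__(self, message: str, *, byte_offset: int, record_index: int):
        super().__init__(
            f"{message} (record {record_index}, byte offset {byte_offset})"
        )
        self.byte_offset = byte_offset
        self.record_index = record_index


class PanelParseError(ValueError):
    """Malformed SNP panel file; carries the 1-based line number."""

    def __init__(self, message: str, *, line_number: int):
        super().__init__(f"{message} (line {line_number})")
        self.line_number = line_number


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: identifier, bases and optional per-base qualities."""

    read_id: str
    bases: str
    qualities: Union[str, None] = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.bases) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Chunk:
    """An ordered batch of reads transferred in one request."""

    reads: tuple
    total_bases: int = field(init=False)

    def __init__(self, reads: Iterable[SequenceRead]):
        object.__setattr__(self, "reads", tuple(reads))
        object.__setattr__(
            self, "total_bases", sum(len(r) for r in self.reads)
        )

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SnpPanel:
    """Genotyping-array positions: unique (sequence_name, 1-based position) pairs."""

    entries: tuple

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self, sequence_name: str) -> list:
        """Sorted 1-based positions on one sequence."""
        return sorted(p for name, p in self.entries if name == sequence_name)


def _open_maybe_gzip(source: Union[str, Path, BinaryIO]) -> BinaryIO:
    """Open a path or binary stream, transparently decompressing gzip.

    Detection uses the gzip magic bytes, not the file name.
    """
    if isinstance(source, (str, Path)):
        handle: BinaryIO = open(source, "rb")
    else:
        handle = source
    buffered = io.BufferedReader(handle) if not isinstance(
        handle, io.BufferedReader
    ) else handle
    if buffered.peek(2)[:2] == _GZIP_MAGIC:
        return gzip.GzipFile(fileobj=buffered)  # type: ignore[return-value]
    return buffered


def read_fastq(source: Union[str, Path, BinaryIO]) -> Iterator[SequenceRead]:
    """Lazily yield reads from a FASTQ file or binary stream (gzip auto-detected).

    Raises :class:`FastqParseError` with the byte offset (into the
    decompressed stream) and record index of the first malformed 4-line group.
    """
    handle = _open_maybe_gzip(source)
    offset = 0
    record_index = 0
    while True:
        record_offset = offset
        header = handle.readline()
        if not header:
            return
        offset += len(header)
        lines = []
        for _ in range(3):
            line = handle.readline()
            offset += len(line)
            lines.append(line)
        seq_line, plus_line, qual_line = lines
        if not qual_line:
            raise FastqParseError(
                "truncated FASTQ record",
                byte_offset=record_offset,
                record_index=record_index,
            )
        header_s = header.decode("ascii").rstrip("\r\n")
        if not header_s.startswith("@"):
            raise FastqParseError(
                f"expected '@' header, got {header_s[:30]!r}",
                byte_offset=record_offset,
                record_index=record_index,
            )
        if not plus_line.decode("ascii").startswith("+"):
            raise FastqParseError(
                "expected '+' separator line",
                byte_offset=record_offset,
                record_index=record_index,
            )
        bases = seq_line.decode("ascii").rstrip("\r\n")
        quals = qual_line.decode("ascii").rstrip("\r\n")
        read_id = header_s[1:].split()[0] if len(header_s) > 1 else ""
        try:
            yield SequenceRead(read_id=read_id, bases=bases, qualities=quals)
        except ValueError as exc:
            raise FastqParseError(
                str(exc), byte_offset=record_offset, record_index=record_index
            ) from exc
        record_index += 1


def write_fastq(reads: Iterable[SequenceRead], sink: Union[str, Path, BinaryIO]) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written.

    Reads lacking qualities (FASTA-derived) get a constant placeholder 'I'.
    """
    own = isinstance(sink, (str, Path))
    handle: BinaryIO = open(sink, "wb") if own else sink  # type: ignore[assignment]
    n = 0
    try:
        for read in reads:
            quals = read.qualities if read.qualities is not None else "I" * len(read)
            handle.write(
                f"@{read.read_id}\n{read.bases}\n+\n{quals}\n".encode("ascii")
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n


def read_fasta(source: Union[str, Path]) -> dict:
    """Load FASTA into an ordered {name: uppercase sequence} dict (Biopython)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")
    }


def write_fasta(sequences: dict, sink: Union[str, Path]) -> None:
    """Write {name: sequence} as wrapped FASTA (Biopython)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(sink), "fasta")


def chunk_stream(
    reads: Iterable[SequenceRead], chunk_size: int
) -> Iterator[Chunk]:
    """Pack a read stream into chunks of at most ``chunk_size`` bases.

    Reads are never split. A chunk closes when the next read would push its
    total past ``chunk_size``; a single read longer than ``chunk_size`` is
    emitted as its own chunk (the server applies its oversized-read rule to
    it). Concatenating the chunks reproduces the input order exactly.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    pending: list = []
    pending_bases = 0
    for read in reads:
        if pending and pending_bases + len(read) > chunk_size:
            yield Chunk(pending)
            pending, pending_bases = [], 0
        pending.append(read)
        pending_bases += len(read)
        if pending_bases >= chunk_size:
            yield Chunk(pending)
            pending, pending_bases = [], 0
    if pending:
        yield Chunk(pending)


def load_snp_panel(source: Union[str, Path]) -> SnpPanel:
    """Load a SNP panel from 2-column TSV (name, 1-based position) or BED.

    BED rows (0-based half-open) are converted to 1-based positions; an
    interval of width w contributes w consecutive positions. Duplicate
    entries are removed and the count logged.
    """
    entries: list = []
    seen = set()
    duplicates = 0
    with open(source, "rt", encoding="ascii") as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 2:
                name, pos_s = fields
                positions = [_parse_position(pos_s, line_number)]
            elif len(fields) >= 3:
                name = fields[0]
                start = _parse_position(fields[1], line_number, zero_ok=True)
                end = _parse_position(fields[2], line_number)
                if end <= start:
                    raise PanelParseError(
                        f"empty BED interval {start}-{end}", line_number=line_number
                    )
                positions = list(range(start + 1, end + 1))
            else:
                raise PanelParseError(
                    f"expected 2 (TSV) or 3+ (BED) columns, got {len(fields)}",
                    line_number=line_number,
                )
            for pos in positions:
                key = (name, pos)
                if key in seen:
                    duplicates += 1
                else:
                    seen.add(key)
                    entries.append(key)
    if duplicates:
        logger.info("load_snp_panel: removed %d duplicate entries", duplicates)
    return SnpPanel(entries=tuple(entries))


def _parse_position(text: str, line_number: int, zero_ok: bool = False) -> int:
    try:
        value = int(text)
    except ValueError:
        raise PanelParseError(
            f"non-integer position {text!r}", line_number=line_number
        ) from None
    if value < 0 or (value == 0 and not zero_ok):
        raise PanelParseError(
            f"non-positive position {value}", line_number=line_number
        )
    return value
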