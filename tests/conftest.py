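"""Shared fixtures: small synthetic references and mappers.

Reference genomes are deliberately small (tens of kilobases) so k-mer index
builds stay fast; they are regenerated from fixed seeds, never stored.
"""

import io

import pytest

from streamdeplete import (
    Chunk,
    DepletionMode,
    ReferenceSet,
    SeedMatchMapper,
    write_fastq,
)
from streamdeplete.simdata import generate_genome


@pytest.fixture(scope="session")
def host_genome():
    return generate_genome(50_000, seed=11, name="host_chr1")


@pytest.fixture(scope="session")
def pathogen_genome():
    return generate_genome(20_000, seed=12, name="pathogen_chr1")


@pytest.fixture(scope="session")
def refs(host_genome, pathogen_genome):
    return ReferenceSet(
        host_sequences={host_genome[0]: host_genome[1]},
        pathogen_sequences={pathogen_genome[0]: pathogen_genome[1]},
    )


@pytest.fixture(scope="session")
def mappers(refs):
    """One seed mapper per depletion mode, sharing the session references."""
    return {mode: SeedMatchMapper(refs, mode) for mode in DepletionMode}


@pytest.fixture
def fastq_bytes():
    """Serialize reads to an in-memory FASTQ stream."""

    def _serialize(reads) -> io.BytesIO:
        buf = io.BytesIO()
        write_fastq(reads, buf)
        buf.seek(0)
        return buf

    return _serialize


@pytest.fixture
def make_chunk():
    return lambda reads: Chunk(reads)
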