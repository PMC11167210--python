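"""End-to-end protocol tests: HTTP server, workers, throttling client."""

import json
import time
import urllib.error
import urllib.request

import pytest

from streamdeplete import (
    Chunk,
    DepletionMode,
    DepletionService,
    SequenceRead,
    ServerConfig,
    start_http_server,
    upload_file,
    write_fastq,
)
from streamdeplete.client import HttpTransport, TransferError
from streamdeplete.depletion import Mapper
from streamdeplete.sequence_io import read_fastq
from streamdeplete.simdata import ReadProfile, sample_reads


@pytest.fixture
def service_factory(mappers):
    """Start services/HTTP servers bound to the session mapper; auto-teardown."""
    started = []

    def _start(mode=DepletionMode.HOST_COMPETITIVE_RETENTION, mapper=None, **cfg):
        cfg.setdefault("buffer_max", 1_000_000)
        cfg.setdefault("chunk_size_hint", 20_000)
        cfg.setdefault("retry_floor", 0.02)
        cfg.setdefault("retry_cap", 0.2)
        config = ServerConfig(mode=mode, **cfg)
        service = DepletionService(config, mapper=mapper or mappers[mode]).start()
        httpd = start_http_server(service)
        started.append((service, httpd))
        url = f"http://127.0.0.1:{httpd.server_address[1]}"
        return service, url

    yield _start
    for service, httpd in started:
        httpd.shutdown()
        service.stop()


def fastq_file(tmp_path, reads, name="reads.fastq"):
    path = tmp_path / name
    with open(path, "wb") as handle:
        write_fastq(reads, handle)
    return path


def host_and_pathogen_reads(host_genome, pathogen_genome, n=60, seed=5):
    host_reads, _ = sample_reads(
        host_genome, n, ReadProfile(), error_rate=0.005, seed=seed, id_prefix="h"
    )
    pathogen_reads, _ = sample_reads(
        pathogen_genome, n, ReadProfile(), error_rate=0.005, seed=seed + 1,
        id_prefix="p",
    )
    return host_reads, pathogen_reads


class TestProtocol:
    def test_contexts_are_independent(self, service_factory):
        service, url = service_factory()
        transport = HttpTransport(url)
        a = transport.create_context()
        b = transport.create_context()
        assert a["context_id"] != b["context_id"]
        assert a["buffer_max"] == b["buffer_max"] == 1_000_000

    def test_unknown_context_is_404(self, service_factory):
        _, url = service_factory()
        transport = HttpTransport(url)
        status, _ = transport.submit(
            "nope", Chunk([SequenceRead("r", "ACGT")])
        )
        assert status == 404
        assert transport.close("nope")[0] == 404

    def test_malformed_payload_is_400(self, service_factory):
        _, url = service_factory()
        transport = HttpTransport(url)
        ctx = transport.create_context()
        req = urllib.request.Request(
            f"{url}/api/context/{ctx['context_id']}/reads",
            data=json.dumps({"reads": [{"id": "r"}]}).encode(),
            method="POST",
            headers={"Content-Type": "application/json"},
        )
        with pytest.raises(urllib.error.HTTPError) as exc:
            urllib.request.urlopen(req)
        assert exc.value.code == 400

    def test_close_immediately_after_create_is_all_zero(self, service_factory):
        service, url = service_factory()
        transport = HttpTransport(url)
        ctx = transport.create_context()
        status, summary = transport.close(ctx["context_id"])
        assert status == 200
        assert summary["received_reads"] == 0
        assert summary["retained_ids"] == []
        # closing frees the context
        assert transport.close(ctx["context_id"])[0] == 404

    def test_context_limit_refused(self, service_factory):
        _, url = service_factory(max_contexts=1)
        transport = HttpTransport(url)
        transport.create_context()
        with pytest.raises(TransferError):
            transport.create_context()


class TestEndToEnd:
    def test_pure_pathogen_upload_retains_everything(
        self, service_factory, tmp_path, host_genome, pathogen_genome
    ):
        _, pathogen_reads = host_and_pathogen_reads(host_genome, pathogen_genome)
        path = fastq_file(tmp_path, pathogen_reads)
        _, url = service_factory(mode=DepletionMode.SIMPLE_PATHOGEN_RETENTION)
        report = upload_file(path, server_url=url)
        assert report.complete
        assert set(report.retained_ids) == {r.read_id for r in pathogen_reads}
        assert report.discarded_reads == 0

    def test_pure_host_upload_is_fully_discarded(
        self, service_factory, tmp_path, host_genome, pathogen_genome
    ):
        host_reads, _ = host_and_pathogen_reads(host_genome, pathogen_genome)
        path = fastq_file(tmp_path, host_reads)
        _, url = service_factory(mode=DepletionMode.HOST_SUBTRACTION)
        report = upload_file(path, server_url=url)
        assert report.complete
        assert report.retained_ids == []
        assert report.discarded_reads == len(host_reads)

    def test_retained_ids_deterministic_across_identical_uploads(
        self, service_factory, tmp_path, host_genome, pathogen_genome
    ):
        host_reads, pathogen_reads = host_and_pathogen_reads(
            host_genome, pathogen_genome
        )
        path = fastq_file(tmp_path, host_reads + pathogen_reads)
        _, url = service_factory()
        first = upload_file(path, server_url=url)
        second = upload_file(path, server_url=url)
        assert set(first.retained_ids) == set(second.retained_ids)

    def test_server_receives_reads_in_file_order(
        self, service_factory, tmp_path, pathogen_genome
    ):
        reads, _ = sample_reads(
            pathogen_genome, 200, ReadProfile(), 0.0, seed=9, id_prefix="ord"
        )
        seen = []
        service, url = service_factory(worker_threads=1)
        inner = service.mapper

        class RecordingMapper(Mapper):
            def map_chunk(self, chunk_reads):
                seen.extend(r.read_id for r in chunk_reads)
                return inner.map_chunk(chunk_reads)

        service.mapper = RecordingMapper()
        path = fastq_file(tmp_path, reads)
        report = upload_file(path, server_url=url, chunk_size=5_000)
        assert report.complete
        assert seen == [r.read_id for r in reads]

    def test_two_contexts_never_mix_reads(
        self, service_factory, tmp_path, host_genome, pathogen_genome
    ):
        _, pathogen_reads = host_and_pathogen_reads(host_genome, pathogen_genome)
        half = len(pathogen_reads) // 2
        file_a = fastq_file(tmp_path, pathogen_reads[:half], "a.fastq")
        file_b = fastq_file(tmp_path, pathogen_reads[half:], "b.fastq")
        service, url = service_factory(
            persist_retained=True, output_dir=str(tmp_path / "out")
        )
        report_a = upload_file(file_a, server_url=url)
        report_b = upload_file(file_b, server_url=url)
        ids_a = {r.read_id for r in pathogen_reads[:half]}
        ids_b = {r.read_id for r in pathogen_reads[half:]}
        assert set(report_a.retained_ids) == ids_a
        assert set(report_b.retained_ids) == ids_b
        outputs = sorted((tmp_path / "out").glob("*.fastq"))
        assert len(outputs) == 2
        per_file = [{r.read_id for r in read_fastq(p)} for p in outputs]
        assert {frozenset(s) for s in per_file} == {
            frozenset(ids_a),
            frozenset(ids_b),
        }

    def test_discarded_read_content_never_reaches_disk(
        self, service_factory, tmp_path, host_genome, pathogen_genome
    ):
        host_reads, pathogen_reads = host_and_pathogen_reads(
            host_genome, pathogen_genome
        )
        path = fastq_file(tmp_path, host_reads + pathogen_reads)
        out_dir = tmp_path / "out"
        _, url = service_factory(persist_retained=True, output_dir=str(out_dir))
        report = upload_file(path, server_url=url)
        assert report.complete
        host_ids = {r.read_id for r in host_reads}
        host_bases = {r.bases for r in host_reads}
        for output in out_dir.glob("*.fastq"):
            for read in read_fastq(output):
                assert read.read_id not in host_ids
                assert read.bases not in host_bases

    def test_oversized_read_reported_as_filtered(
        self, service_factory, tmp_path, pathogen_genome
    ):
        reads, _ = sample_reads(
            pathogen_genome, 10, ReadProfile(), 0.0, seed=13, id_prefix="ok"
        )
        big = SequenceRead("too_big", pathogen_genome[1][:6_000])
        path = fastq_file(tmp_path, reads + [big])
        _, url = service_factory(buffer_max=5_000, chunk_size_hint=2_000)
        report = upload_file(path, server_url=url)
        assert report.oversize_rejected_reads == 1
        assert report.complete
        assert "too_big" not in (report.retained_ids or [])


class SlowMapper(Mapper):
    """Delays each chunk to force throttling."""

    def __init__(self, inner, delay):
        self.inner = inner
        self.delay = delay

    def map_chunk(self, reads):
        time.sleep(self.delay)
        return self.inner.map_chunk(reads)


class TestThrottling:
    def test_small_buffer_with_slow_worker_throttles_then_completes(
        self, service_factory, tmp_path, pathogen_genome, mappers
    ):
        reads, _ = sample_reads(
            pathogen_genome, 300, ReadProfile(), 0.0, seed=17, id_prefix="t"
        )
        path = fastq_file(tmp_path, reads)
        mode = DepletionMode.SIMPLE_PATHOGEN_RETENTION
        _, url = service_factory(
            mode=mode,
            mapper=SlowMapper(mappers[mode], delay=0.05),
            buffer_max=10_000,
            chunk_size_hint=5_000,
        )
        report = upload_file(path, server_url=url, jitter_seed=1)
        assert report.retries > 0
        assert report.complete
        assert report.sent_reads == len(reads)

    def test_client_waits_at_least_the_advised_retry_after(self):
        """Backoff compliance on a mock transport with a mock clock."""
        sleeps = []

        class ThrottlingTransport:
            def __init__(self):
                self.calls = 0

            def create_context(self):
                return {"context_id": "c", "buffer_max": 100, "chunk_size_hint": 50}

            def submit(self, context_id, chunk):
                self.calls += 1
                if self.calls <= 3:
                    return 429, {"retry_after": 5.0}
                return 200, {"occupancy": 0, "oversize_rejected": []}

            def close(self, context_id):
                return 200, {
                    "retained_reads": 1, "discarded_reads": 0,
                    "oversize_rejected_reads": 0, "retained_ids": ["r0"],
                }

        import io

        buf = io.BytesIO(b"@r0\nACGT\n+\nIIII\n")
        report = upload_file(
            buf,
            transport=ThrottlingTransport(),
            chunk_size=50,
            sleep=sleeps.append,
            jitter_seed=3,
            clock=lambda: 0.0,
        )
        assert report.retries == 3
        assert all(s >= 5.0 for s in sleeps)
        assert report.complete

    def test_max_retries_aborts_with_partial_report(self):
        class AlwaysFull:
            def create_context(self):
                return {"context_id": "c", "buffer_max": 100, "chunk_size_hint": 50}

            def submit(self, context_id, chunk):
                return 429, {"retry_after": 0.01}

            def close(self, context_id):
                return 200, {
                    "retained_reads": 0, "discarded_reads": 0,
                    "oversize_rejected_reads": 0, "retained_ids": [],
                }

        import io

        buf = io.BytesIO(b"@r0\nACGT\n+\nIIII\n")
        with pytest.raises(TransferError) as exc:
            upload_file(
                buf, transport=AlwaysFull(), chunk_size=50,
                max_retries=2, sleep=lambda s: None,
            )
        assert exc.value.context_id == "c"
        assert exc.value.report.retries == 3


class TestWorkerFaults:
    def test_mapper_crash_counts_reads_as_discarded(
        self, service_factory, tmp_path, pathogen_genome, mappers
    ):
        class CrashingMapper(Mapper):
            def map_chunk(self, reads):
                raise RuntimeError("boom")

        reads, _ = sample_reads(
            pathogen_genome, 20, ReadProfile(), 0.0, seed=19, id_prefix="crash"
        )
        path = fastq_file(tmp_path, reads)
        mode = DepletionMode.SIMPLE_PATHOGEN_RETENTION
        _, url = service_factory(mode=mode, mapper=CrashingMapper())
        report = upload_file(path, server_url=url)
        assert report.complete
        assert report.retained_reads == 0
        assert report.discarded_reads == len(reads)
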