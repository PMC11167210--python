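# Methods

## Protocol and buffer semantics

An upload is a *context*: a server-side object holding a FIFO queue of
un-depleted chunks, an occupancy counter in bases, monotone read counters,
and the retained-read IDs. The privacy bound is enforced at admission: a
chunk is accepted iff `occupancy + chunk_bases <= buffer_max`, checked and
applied as one atomic step under the context lock, and admission is
all-or-nothing per chunk (no partial acceptance). Occupancy is decremented
when a chunk is *dispatched* to the mapper, not when mapping completes.
Consequence, stated openly: bases in flight inside a mapper are outside the
bound, at most one chunk per worker thread; configurations where
`chunk_size_hint > buffer_max` are warned against at startup. Chunk size is
measured in bases (not reads or bytes) because bases are the unit of the
buffer bound; clients are advised a default chunk of 20,000 bases, within
the 5,000–50,000 range where chunking overhead and retry-calibration
granularity balance.

A single read longer than the entire buffer can never be admitted; it is
rejected on arrival, counted as filtered, and reported back — the client
does not silently drop it. Reads longer than the buffer arriving inside a
multi-read chunk would make that chunk permanently inadmissible, so the
service strips them out and applies the same rejected-as-filtered rule
before admitting the remainder; a throttled request changes no state, which
makes client retries idempotent.

Retry-after is `clamp(ceil(needed_bases / rate), floor, cap)` with
`floor = 1 s`, `cap = 60 s`, where `rate` is an exponential moving average
(`alpha = 0.3`, first observation replaces the configured prior of
100,000 bases/s) of per-chunk mapping throughput. These constants are
configuration, not science; the EMA calibration itself is this package's
design choice, as is the ±20% *additive* retry jitter (the client never
resends before the advised wait — that direction is asserted by test).

Conservation is an invariant: at close,
`received = retained + discarded + oversize_rejected`. Close drains the
queue (waits on the context condition variable), optionally persists
retained reads as `{context_id}.fastq`, and frees the context. Idle
contexts can be garbage-collected after a TTL. The context store ships one
backend, the in-process thread-safe registry; the store contract (atomic
check-and-increment, per-context FIFO, round-robin dispatch) is what any
external key-value backend would have to provide.

## Classification rules

Only the primary (best) alignment of a read is consulted. A read is
"confidently aligned" iff it is mapped with MAPQ >= the threshold (default
20, configurable). The per-mode truth table — this package's
interpretation, enumerated against a brute-force oracle in the tests:

| mode | retain | discard |
|---|---|---|
| host_subtraction | unmapped, sub-threshold, or non-host | confident host hit |
| simple_pathogen_retention | confident pathogen hit | everything else |
| host_competitive_retention | confident pathogen-primary hit | host-primary, unmapped, sub-threshold |

Sub-threshold mappings are treated as unaligned in *every* mode; for the
retention modes this is the privacy-conservative reading (such reads are
discarded). Equal-score host/pathogen placements in competitive mode
resolve to host, again the conservative direction. Paired-end mates are
treated as independent single-end reads.

## Mappers

Two interchangeable backends implement the mapper interface:

* **SeedMatchMapper** (default): indexes every k-mer (k = 21) of the
  mode-appropriate references; a read votes with its k-mers (stride 3, both
  strands) for (sequence, strand, diagonal) candidates, and MAPQ is
  `60·(best − second)/best` capped at 60 — a unique placement scores 60, an
  exact tie 0, so ambiguous reads fall under the default threshold. It
  tolerates substitution errors but not indels, which matches the synthetic
  data generator; it is a genuine mapper for that data class, not a mock.
* **Minimap2Mapper**: batches each chunk through the `minimap2` executable
  (`-a --secondary=no`, preset `sr` or `map-ont`) and parses primary SAM
  records with pysam. A test cross-checks the two backends' class calls on
  noisy synthetic reads (>= 95% agreement required).

## Risk model

Worst case is hard-coded: every buffered base is treated as human. With `S`
panel sites on a genome of `G` bases and `n` uniformly placed reads of
length `L`, a fixed site is covered by one read with probability `L/G`
(edge effects of order `L/G` are avoided by placing reads entirely on the
genome, i.e. resampling rather than wrapping), so the covered-site count is
`Binomial(S, 1 − (1 − L/G)^n)` with expectation

    E = S · (1 − (1 − L/G)^n),   n = floor(B/L),

to which the implementation adds the exact factor `(1 − r/G)` for the
trimmed last read of length `r = B − nL`; the two coincide whenever `L`
divides `B`. For `B ≪ G` this is `≈ S·B/G` (verified to <1% on a parameter
grid for `B/G < 1e-3`). With varying read lengths the closed form is used
with `E[L]`; in the low-coverage regime the expectation depends only on the
total buffered bases, so this caveat is mild, and the long-read case is
checked against the simulator.

The Monte-Carlo simulator follows the empirical protocol exactly: draw
uniform read placements until cumulative length equals the buffer size,
trimming the last read, and count distinct covered panel positions. It is
positions-only (no sequence data), so human-scale parameters — 2,372,000
panel sites on 3.1 Gb, the package's human-like constants — run in
milliseconds per replicate. The buffer advisor exploits monotonicity of the
expectation in `B`: geometric growth to bracket, then integer bisection to
1-base resolution, returning the largest buffer whose expectation meets the
target (or the cap, flagged, when every size does).

At human-like density the model predicts ~7.7 expected covered SNPs for a
10,000-base buffer and ~77 for 100,000 bases. The covered count is
approximately Poisson at these densities, so the 95th percentile at 10 kb
sits at 12–13 — above the round bound of 10 that holds "in almost all"
small replicate sets; the corresponding acceptance check is left failing
rather than loosened, since it follows directly from the model this package
itself implements. At 100 kb the ≤100 bound holds with ~99.6% probability.

## Synthetic data

The generator emulates a contaminated clinical isolate transfer: default
datasets of 10^4 reads at 1% human fraction (the mixture count is exact:
`round(n·fraction)`), 0.5% per-base substitution noise, short-read profile
of fixed 150 b or long-read log-normal lengths (median 2,000 b, sigma 0.6
— desk-scale stand-ins for Illumina and nanopore length regimes). Host
stand-in genomes default to 1 Mb and pathogen genomes to 100 kb — two to
three orders of magnitude below real references, enough for mapping to be
unambiguous while keeping k-mer indexes instant. Homopolymer runs are
capped at 20 bases so seed mappers keep unique placements. Every generator
is a pure function of its seed; truth labels partition each dataset
exactly.

What this synthetic data does *not* model: indels and quality-dependent
platform error, repeats and low-complexity sequence, shared k-mers between
host and pathogen, and real human population variation. Passing the
accuracy tests therefore demonstrates the *plumbing* — no read is lost,
leaked, or misrouted, and classification follows the mode rules — at an
easier mapping difficulty than real genomes; the accuracy percentages here
(~100%) sit at the top of the 96–100% range expected with real references,
not as evidence about real-data difficulty.

## Problem sizes and numerical choices

Test and acceptance runs use 10^3–10^4-read datasets, 200-replicate risk
simulations, and 400–1,000-replicate model-vs-simulation comparisons; these
sizes give standard errors comfortably inside the asserted 3-SE bands while
keeping the whole suite around a minute. Stochastic assertions use fixed
seeds; the acceptance script derives all of its seeds from its `--seed`
argument. Degenerate inputs are defined, not errors: empty FASTQ yields an
empty stream, `B = 0` or `S = 0` yield zero risk, an empty chunk queue
dispatches nothing.

## Known limitations

Single-server, volatile buffer (deliberately so — persistence would defeat
the guarantee); no TLS/authentication; no k-mer prescreening or read
splitting for oversized reads; covered-SNP count is a pragmatic proxy for
re-identifiability, not a formal identifiability analysis; linkage between
panel sites is ignored.
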