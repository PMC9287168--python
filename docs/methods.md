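# Methods

This note documents the data model, the codec pipeline, the container and
index layouts, the synthetic-data generator, and the numerical and design
choices behind slow5kit — including what a passing test does and does not
establish.

## Data model

A signal file holds a header and a sequence of records. The header carries
the format version, the number of *read groups* (one group per sequencing
run), an ordered map of per-group attribute strings (flow cell id, ASIC id,
run id, experiment start time, ...), and the column schema. The primary
schema is fixed — eight columns:

| column | type | meaning |
|---|---|---|
| `read_id` | `char*` | unique read identifier |
| `read_group` | `uint32_t` | index into the header's group metadata |
| `digitisation` | `double` | number of ADC quantisation levels |
| `offset` | `double` | ADC offset, in ADC units |
| `range` | `double` | current span in pA |
| `sampling_rate` | `double` | samples per second |
| `len_raw_signal` | `uint64_t` | sample count |
| `raw_signal` | `int16_t*` | the ADC trace |

ADC values convert to picoamperes as `(raw + offset) × range /
digitisation`. Auxiliary columns are declared in the header with C-style
type tags (`int8_t`…`uint64_t`, `float`, `double`, `char`, `char*`, and
`*`-suffixed array forms of the numeric tags); no canonical list of
auxiliary names is imposed, since instrument software versions disagree on
them. A missing auxiliary value is a sentinel rendered `.` in ASCII.

Record validation is *total*: `validate_record` returns a list of named
violations and never raises, so malformed streaming input is data, not an
exception. Read-id uniqueness is enforced at file write and index build
time rather than at record construction, so streaming producers are never
blocked by global state.

## ASCII dialect

Tab-separated columns, newline rows, `#` structural rows, `@` attribute
rows (one tab-separated value per read group — a convention chosen here;
the multi-group rendering of attribute rows has no single published
reference), comma-separated signal. Doubles are written in the shortest
form that round-trips, with integral values printed without a decimal
point; round-trip equality (`parse(write(x)) == x`) is the contract the
test suite enforces, rather than byte-stability of arbitrary third-party
input. An empty signal is an empty cell with `len_raw_signal` 0. Read ids
may not contain tab, newline, carriage return or comma (delimiter
integrity). Files are UTF-8, written with `\n` and tolerant of CRLF on
read. The parser is single-pass and constant-memory per record.

## Signal codec

The signal path is `delta → zigzag → StreamVByte`:

1. **Delta.** `d[0] = s[0]`, `d[i] = s[i] − s[i−1]`, computed in int16 with
   wrap-around (mod 2¹⁶). Plain differences of int16 values can need 17
   bits (e.g. −32768 → 32767); wrapping keeps every delta in 16 bits and is
   exactly invertible for int16 input, making the codec total over all
   signals rather than only over smooth ones.
2. **Zig-zag.** `0, −1, 1, −2, … → 0, 1, 2, 3, …`, i.e.
   `(v << 1) XOR (v >> 15)` at 16-bit width, so small-magnitude deltas of
   either sign become small unsigned values.
3. **StreamVByte.** A two-width Group-Varint variant: one control bit per
   value (LSB-first within each control byte) selecting a 1- or 2-byte
   little-endian payload; the value count is stored explicitly ahead of the
   control stream, so trailing control bits are ignorable. Encoded size is
   exactly `ceil(n/8) + n + popcount(control)`. Classic StreamVByte uses
   2 control bits and four widths for 32-bit input; the input here is
   int16, so two widths suffice and cost one control bit instead of two.
   The layout is self-defined and version-tagged in the container; no
   byte-compatibility with other StreamVByte implementations is claimed.

Record-level compression (zlib level 6, or zstd level 1 — speed-oriented,
matching the format's parallel-access goal; both configurable) is applied
over the whole serialised record as **one independent stream per record**.
Independence is the load-bearing property: decompressing record *k* needs
no bytes from any other record, which is what lets indexed readers fetch
records concurrently. zstd-over-svb is the `vbz` preset. The zstd binding
is `numcodecs.Zstd`; an empty payload is represented by an empty stream
for every method (the binding cannot round-trip a zero-length frame, and a
zero-length compressed stream is unambiguous).

## Binary container

Little-endian throughout. Prelude: 8 magic bytes (`BLOW5` + `01 00 00`),
a 3-byte layout version, one method byte each for record and signal
compression, the group count, then the length-prefixed ASCII header text,
stored uncompressed and identical to the ASCII rendering (one header
serialiser, trivially diffable). Records follow as length-prefixed frames;
the file ends with the magic reversed as an end-of-file sentinel, so
truncation is always detectable and reported with the last good offset.
Inside a frame, the signal blob carries its own 8-byte length so frames
are skippable without a signal decode. Readers reject layout major
versions above their own, and bound every declared frame length by the
file size before allocating. Writing is streaming: one record buffered at
a time.

## Index and parallel access

The index file maps read id → (byte offset, byte length): magic
`S5IDX` + version byte, the data file's size and an 8-byte BLAKE2b digest
of its header block (cheap staleness detection for the
regenerated-data-file hazard), then per-entry `u16 id length, id, u64
offset, u64 length`, and a trailing entry count — append-friendly, O(n)
load into a hash map. For ASCII data the entry covers the record's line
without its terminator; for BLOW5, the whole frame including its length
prefix. Discovery convention: `<data path>.idx`.

Random access opens the data file once and serves every fetch with
`os.pread(fd, length, offset)`. `pread` takes an explicit offset and never
touches the shared file position, so any number of threads can read
through one descriptor with no mutual exclusion; the retrieved record
multiset is invariant to worker count and scheduling, and the test suite
asserts that invariance on content checksums.

## Merge, split, conversion

Merge collapses read groups with identical attribute maps into one and
otherwise numbers groups by first occurrence in input order
(deterministic); records are remapped and otherwise unchanged. When merged
groups have different attribute name sets, a group missing an attribute
gets the empty string. Duplicate read ids across inputs and conflicting
format major versions are errors. Split by group emits single-group files
renumbered to group 0; split by reads emits fixed-size chunks with the
header copied; split-then-merge is content-equal to the original.
FAST5 conversion targets the multi-read layout (`read_<id>/Raw/Signal`,
`channel_id` calibration attributes, `tracking_id` run metadata, grouped
into read groups by identical tracking maps); the attribute mapping is a
module-level table users can extend. Single-read containers are rejected
with an explicit message. Conversion work is partitioned at file
granularity, and losslessness is asserted as a fixed point:
`f2s(s2f(f2s(x))) == f2s(x)`.

## Benchmark harness

`cpu_utilisation = cpu_time / (wall_time × n_threads) × 100` (normalised:
100% means every requested thread was busy); `core_hours = n_threads ×
wall_hours`, constant under ideal parallel scaling. The access harness
samples read ids with an explicit seed recorded in the report, partitions
them round-robin across workers, and reports throughput plus both
formulas. Timing numbers describe the machine they ran on and are never
asserted; correctness is asserted on the content checksum only. Clearing
the OS page cache portably requires privileges the library should not
assume, so the harness instead accepts a `pre_run_hook` callable for users
who need cold-cache measurements — warm-cache numbers overstate absolute
throughput but do not affect any content assertion.

## Synthetic data

The generator emulates the one statistical property of nanopore current
that the codec depends on: local smoothness. Signals are integer random
walks, `s[i] = s[i−1] + round(N(0, σ))` with σ = 5 ADC units, started
around `N(500, 30)` and clipped to int16; lengths are
`N(mean, mean/4)` truncated at 1 sample (mean 2000 by default, so a
1000-read fixture carries ~2M samples); calibration constants are drawn
once per read group (digitisation 8192, sampling rate 4000, range
~1100–1500 pA, small integer offsets — typical instrument values).
Everything is a pure function of the seed.

What this does **not** emulate: pore-model level structure, event
segmentation, adapter/stall artefacts, or any sequence content. A green
compression-ordering test therefore establishes that vbz beats plain zlib
on locally smooth signals — the mechanism the codec is built on — not any
particular savings ratio on real instrument data, which depends on read
length and metadata overhead. Likewise the worked-example file's signals
are exact only in their printed two-value prefixes; the remainder pads
with the last printed value to reach the stated lengths, so length
arithmetic is exact while value checks use only the prefixes.

## Numerical and degenerate-input choices

- Doubles survive ASCII round trips exactly (shortest-repr formatting) and
  binary round trips exactly (IEEE-754 LE).
- Empty files (header only) are valid everywhere: they index to zero
  entries, split by group to header-only parts, and report zero-count
  stats.
- Signals with extreme jumps wrap in the delta stage (see above) and still
  round-trip bit-exactly.
- Corrupt containers fail with positioned errors: bad magic, unknown
  method bytes, frame lengths exceeding the file, and missing sentinels
  are distinguished.

## Known limitations

- The container, index and StreamVByte byte layouts are clean-room and
  version-tagged; files from other SLOW5-ecosystem software are out of
  scope on both read and write.
- The Python conversion path holds one FAST5 file's records in memory at a
  time and parallelises across files with threads; it is a correctness
  surface, not a throughput claim.
- Absolute throughput, speed-up factors and wall-clock comparisons across
  storage systems are hardware properties and are deliberately outside the
  test surface.
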