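"""Core domain types for the SLOW5/BLOW5 nanopore raw-signal format.

SLOW5 stores one nanopore read per record: a read identifier, the read-group
index tying the read to one sequencing run's metadata, four calibration
constants (``digitisation``, ``offset``, ``range``, ``sampling_rate``) and the
raw 16-bit ADC current trace.  The header carries global metadata: the format
version, the number of read groups, and per-group attribute strings (flow cell
id, ASIC id, run id, ...).

The primary column schema is fixed; auxiliary columns are declared in the
header with C-style type tags and may be missing per record (rendered as a
``.`` sentinel in ASCII).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class Slow5Error(Exception):
    """Base class for all errors raised by this package."""


class FormatError(Slow5Error):
    """A file or line does not conform to the SLOW5/BLOW5 grammar."""


class SchemaError(Slow5Error):
    """Header structure is invalid (arity, column schema, type tags)."""


class ValidationError(Slow5Error):
    """A record violates its invariants against the header."""


class DecodeError(Slow5Error):
    """A binary payload could not be decoded.

    ``offset`` is the byte position (within the payload or file) at which
    decoding failed, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at byte {offset})")
        self.offset = offset


class TruncatedFileError(DecodeError):
    """A container ended before its end-of-file sentinel."""


class UnsupportedCompressionError(Slow5Error):
    """A compression method byte or name is not recognised."""


class DuplicateReadIdError(Slow5Error):
    """The same read_id occurs more than once in one file or merge set."""


class StaleIndexError(Slow5Error):
    """An index file does not match the current data file."""


class ReadNotFoundError(Slow5Error, KeyError):
    """A read_id is absent from an index."""


class UnsupportedFormatError(Slow5Error):
    """Input is a recognised but unsupported container (e.g. single-read FAST5)."""


class UnsupportedEnvironmentError(Slow5Error):
    """A required optional dependency is unavailable."""


# --------------------------------------------------------------------------
# Column schema and auxiliary type tags
# --------------------------------------------------------------------------

PRIMARY_COLUMNS: tuple[str, ...] = (
    "read_id",
    "read_group",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)

PRIMARY_TYPE_TAGS: tuple[str, ...] = (
    "char*",
    "uint32_t",
    "double",
    "double",
    "double",
    "double",
    "uint64_t",
    "int16_t*",
)

#: numpy dtypes for the scalar numeric auxiliary type tags.
NUMERIC_TAG_DTYPES: dict[str, np.dtype] = {
    "int8_t": np.dtype("<i1"),
    "int16_t": np.dtype("<i2"),
    "int32_t": np.dtype("<i4"),
    "int64_t": np.dtype("<i8"),
    "uint8_t": np.dtype("<u1"),
    "uint16_t": np.dtype("<u2"),
    "uint32_t": np.dtype("<u4"),
    "uint64_t": np.dtype("<u8"),
    "float": np.dtype("<f4"),
    "double": np.dtype("<f8"),
}

#: every auxiliary type tag accepted in a header schema.
AUX_TYPE_TAGS: frozenset[str] = frozenset(
    list(NUMERIC_TAG_DTYPES)
    + [t + "*" for t in NUMERIC_TAG_DTYPES]  # array forms
    + ["char", "char*"]  # single character / string
)


class _Missing:
    """Sentinel for an absent auxiliary value (rendered ``.`` in ASCII)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: characters a read_id may not contain (delimiter integrity).
FORBIDDEN_READ_ID_CHARS = ("\t", "\n", "\r", ",")


# --------------------------------------------------------------------------
# Header
# --------------------------------------------------------------------------


@dataclass
class Slow5Header:
    """Global file metadata.

    Parameters
    ----------
    slow5_version
        Dotted version string of the format, e.g. ``"1.0.0"``.
    num_read_groups
        Number of read groups (sequencing runs) described by the header.
    attributes
        Ordered mapping attribute-name -> list of per-group string values.
        Every list must have exactly ``num_read_groups`` entries.
    aux_schema
        Ordered ``(name, type_tag)`` pairs for auxiliary columns; may be empty.
    """

    slow5_version: str = "1.0.0"
    num_read_groups: int = 1
    attributes: dict[str, list[str]] = field(default_factory=dict)
    aux_schema: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.aux_schema = tuple((str(n), str(t)) for n, t in self.aux_schema)

    @property
    def primary_schema(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(PRIMARY_COLUMNS, PRIMARY_TYPE_TAGS))

    @property
    def version_tuple(self) -> tuple[int, ...]:
        return tuple(int(p) for p in self.slow5_version.split("."))

    def validate(self) -> None:
        """Raise :class:`SchemaError` if the header is structurally invalid."""
        try:
            version = self.version_tuple
        except ValueError:
            raise SchemaError(f"malformed slow5_version {self.slow5_version!r}")
        if len(version) != 3:
            raise SchemaError(f"slow5_version must have three components, got {self.slow5_version!r}")
        if self.num_read_groups < 0:
            raise SchemaError("num_read_groups must be non-negative")
        if self.attributes and self.num_read_groups < 1:
            raise SchemaError("a header with attributes must declare at least one read group")
        for name, values in self.attributes.items():
            if len(values) != self.num_read_groups:
                raise SchemaError(
                    f"attribute {name!r} has {len(values)} values for "
                    f"{self.num_read_groups} read group(s)"
                )
        seen = set()
        for name, tag in self.aux_schema:
            if tag not in AUX_TYPE_TAGS:
                raise SchemaError(f"unknown auxiliary type tag {tag!r} for field {name!r}")
            if name in PRIMARY_COLUMNS or name in seen:
                raise SchemaError(f"duplicate column name {name!r}")
            seen.add(name)

    def group_attributes(self, group: int) -> dict[str, str]:
        """Attribute map of a single read group (used for merge collapsing)."""
        if not 0 <= group < self.num_read_groups:
            raise IndexError(f"read group {group} out of range")
        return {name: values[group] for name, values in self.attributes.items()}


# --------------------------------------------------------------------------
# Record
# --------------------------------------------------------------------------


def _aux_equal(a: Any, b: Any) -> bool:
    if a is MISSING or b is MISSING:
        return a is b
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return np.array_equal(np.asarray(a), np.asarray(b))
    return a == b


@dataclass(eq=False)
class Slow5Record:
    """One nanopore read: identity, calibration and the raw current trace.

    ``raw_signal`` holds the 16-bit ADC samples; ``to_picoamps`` converts them
    to physical current using the per-read calibration constants.
    """

    read_id: str
    read_group: int
    digitisation: float
    offset: float
    range: float
    sampling_rate: float
    len_raw_signal: int
    raw_signal: np.ndarray
    aux_values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_signal = np.asarray(self.raw_signal)
        if self.raw_signal.dtype == object or self.raw_signal.ndim == 0:
            self.raw_signal = np.atleast_1d(self.raw_signal)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Slow5Record):
            return NotImplemented
        if (
            self.read_id != other.read_id
            or self.read_group != other.read_group
            or self.digitisation != other.digitisation
            or self.offset != other.offset
            or self.range != other.range
            or self.sampling_rate != other.sampling_rate
            or self.len_raw_signal != other.len_raw_signal
            or not np.array_equal(self.raw_signal, other.raw_signal)
        ):
            return False
        keys = set(self.aux_values) | set(other.aux_values)
        return all(
            _aux_equal(self.aux_values.get(k, MISSING), other.aux_values.get(k, MISSING))
            for k in keys
        )

    def copy(self, **changes: Any) -> "Slow5Record":
        return dataclasses.replace(self, **changes)


def validate_record(record: Slow5Record, header: Slow5Header) -> list[str]:
    """Check a record against its header; return a list of violations.

    Total over malformed inputs: every invariant violation is reported as a
    human-readable string and nothing raises.  An empty list means the record
    is valid.
    """
    violations: list[str] = []
    if not record.read_id:
        violations.append("read_id is empty")
    else:
        for ch in FORBIDDEN_READ_ID_CHARS:
            if ch in record.read_id:
                violations.append(f"read_id contains forbidden character {ch!r}")
    if not 0 <= record.read_group < max(header.num_read_groups, 1):
        violations.append(
            f"read_group {record.read_group} out of range for "
            f"{header.num_read_groups} read group(s)"
        )
    sig = record.raw_signal
    n = int(sig.shape[0]) if sig.ndim == 1 else -1
    if n < 0:
        violations.append("raw_signal is not one-dimensional")
    elif record.len_raw_signal != n:
        violations.append(
            f"len_raw_signal {record.len_raw_signal} does not match "
            f"signal length {n}"
        )
    if sig.size:
        if not np.issubdtype(sig.dtype, np.integer):
            violations.append(f"raw_signal dtype {sig.dtype} is not integer")
        else:
            lo, hi = int(sig.min()), int(sig.max())
            if lo < -32768 or hi > 32767:
                violations.append(
                    f"raw_signal values [{lo}, {hi}] do not fit a signed 16-bit integer"
                )
    if not record.digitisation > 0:
        violations.append(f"digitisation {record.digitisation} is not positive")
    if not record.range > 0:
        violations.append(f"range {record.range} is not positive")
    if not record.sampling_rate > 0:
        violations.append(f"sampling_rate {record.sampling_rate} is not positive")
    aux_names = {name for name, _ in header.aux_schema}
    for name in record.aux_values:
        if name not in aux_names:
            violations.append(f"auxiliary value {name!r} not declared in header schema")
    return violations


def to_picoamps(record: Slow5Record) -> np.ndarray:
    """Convert raw ADC samples to picoamperes.

    pA[i] = (raw[i] + offset) * range / digitisation.
    """
    if not record.digitisation > 0:
        raise ValidationError(
            f"invalid calibration: digitisation {record.digitisation} must be positive"
        )
    sig = np.asarray(record.raw_signal, dtype=np.float64)
    return (sig + record.offset) * record.range / record.digitisation


# --------------------------------------------------------------------------
# Compression configuration
# --------------------------------------------------------------------------


class RecordCompression(str, Enum):
    """Whole-record compression method (one independent stream per record)."""

    NONE = "none"
    ZLIB = "zlib"
    ZSTD = "zstd"


class SignalCompression(str, Enum):
    """Raw-signal codec applied before record compression."""

    NONE = "none"
    SVB = "svb"


@dataclass(frozen=True)
class CompressionConfig:
    """Record-level x signal-level compression choice.

    ``(zstd, svb)`` is the "vbz" preset: StreamVByte on the zig-zagged signal
    deltas, then Zstandard over the whole record.
    """

    record_method: RecordCompression = RecordCompression.NONE
    signal_method: SignalCompression = SignalCompression.NONE

    @classmethod
    def vbz(cls) -> "CompressionConfig":
        return cls(RecordCompression.ZSTD, SignalCompression.SVB)

    @property
    def is_vbz(self) -> bool:
        return (
            self.record_method is RecordCompression.ZSTD
            and self.signal_method is SignalCompression.SVB
        )


#: all six supported combinations, in a stable order.
ALL_CONFIGS: tuple[CompressionConfig, ...] = tuple(
    CompressionConfig(r, s) for r in RecordCompression for s in SignalCompression
)


# --------------------------------------------------------------------------
# Index entry and benchmark report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexEntry:
    """Byte position of one record within a SLOW5/BLOW5 file."""

    read_id: str
    offset: int
    length: int


@dataclass
class BenchReport:
    """Outcome of a timed parallel random-access job.

    ``cpu_utilisation_pct`` is normalised by thread count
    (cpu_time / (wall_time * n_threads) * 100); ``core_hours`` is
    n_threads * wall hours and is constant under ideal parallel scaling.
    Timing fields describe this machine and are never comparable across
    hardware; ``record_checksum`` is content-derived and is the field
    correctness assertions use.
    """

    n_threads: int
    wall_seconds: float
    cpu_seconds: float
    reads_accessed: int
    reads_per_second: float
    cpu_utilisation_pct: float
    core_hours: float
    record_checksum: str = ""
    seed: int | None = None
    not_found: list[str] = field(default_factory=list)
    rep_wall_seconds: list[float] = field(default_factory=list)
    mean_wall_seconds: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
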