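"""The BLOW5 binary container: framed, per-record-compressed signal records.

Layout (all integers little-endian, lengths in bytes)::

    magic            8 bytes   b"BLOW5\\x01\\x00\\x00"
    version          3 bytes   (major, minor, patch) of the container layout
    record_method    1 byte    0 none / 1 zlib / 2 zstd
    signal_method    1 byte    0 none / 1 svb
    num_read_groups  4 bytes   u32
    header_length    8 bytes   u64
    header_text      ...       the ASCII header rendering, UTF-8, uncompressed
    frames           ...       per record: u64 payload length || payload
    sentinel         8 bytes   magic reversed (end-of-file marker)

Each frame payload is the record's field serialisation (signal already
signal-compressed, with its own u64 length so frames are skippable without a
signal decode) compressed as one independent stream, so a frame can be decoded
given only the prelude and that frame's bytes — the contract behind indexed,
lock-free parallel access.  This byte layout is self-defined and
version-tagged; it is not interchange-compatible with other BLOW5 writers.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Any, BinaryIO, Iterable, Iterator

import numpy as np

from . import ascii_io, codecs
from .model import (
    MISSING,
    NUMERIC_TAG_DTYPES,
    CompressionConfig,
    DecodeError,
    DuplicateReadIdError,
    FormatError,
    Slow5Header,
    Slow5Record,
    TruncatedFileError,
    ValidationError,
    validate_record,
)

BLOW5_EXTENSION = ".blow5"
MAGIC = b"BLOW5\x01\x00\x00"
EOF_SENTINEL = bytes(reversed(MAGIC))
LAYOUT_VERSION = (1, 0, 0)

_U16 = struct.Struct("<H")
_U32 = struct.Struct("<I")
_U64 = struct.Struct("<Q")
_F64 = struct.Struct("<d")


# --------------------------------------------------------------------------
# Record payload serialisation
# --------------------------------------------------------------------------


def _encode_aux(buf: io.BytesIO, value: Any, tag: str) -> None:
    if value is MISSING:
        buf.write(b"\x00")
        return
    buf.write(b"\x01")
    if tag == "char":
        buf.write(str(value).encode("utf-8")[:1].ljust(1, b"\x00"))
    elif tag == "char*":
        raw = str(value).encode("utf-8")
        buf.write(_U16.pack(len(raw)))
        buf.write(raw)
    elif tag.endswith("*"):
        arr = np.asarray(value, dtype=NUMERIC_TAG_DTYPES[tag[:-1]])
        buf.write(_U32.pack(arr.size))
        buf.write(arr.tobytes())
    else:
        buf.write(np.asarray(value, dtype=NUMERIC_TAG_DTYPES[tag]).tobytes())


def _decode_aux(view: memoryview, pos: int, tag: str) -> tuple[Any, int]:
    present = view[pos]
    pos += 1
    if present == 0:
        return MISSING, pos
    if tag == "char":
        return bytes(view[pos : pos + 1]).decode("utf-8"), pos + 1
    if tag == "char*":
        (n,) = _U16.unpack_from(view, pos)
        pos += 2
        return bytes(view[pos : pos + n]).decode("utf-8"), pos + n
    if tag.endswith("*"):
        dtype = NUMERIC_TAG_DTYPES[tag[:-1]]
        (n,) = _U32.unpack_from(view, pos)
        pos += 4
        nbytes = n * dtype.itemsize
        arr = np.frombuffer(view[pos : pos + nbytes], dtype=dtype).copy()
        return arr, pos + nbytes
    dtype = NUMERIC_TAG_DTYPES[tag]
    val = np.frombuffer(view[pos : pos + dtype.itemsize], dtype=dtype)[0]
    out = float(val) if dtype.kind == "f" else int(val)
    return out, pos + dtype.itemsize


def encode_record(
    record: Slow5Record, header: Slow5Header, config: CompressionConfig
) -> bytes:
    """Serialise one record to its (record-)compressed frame payload."""
    buf = io.BytesIO()
    rid = record.read_id.encode("utf-8")
    buf.write(_U16.pack(len(rid)))
    buf.write(rid)
    buf.write(_U32.pack(int(record.read_group)))
    for v in (record.digitisation, record.offset, record.range, record.sampling_rate):
        buf.write(_F64.pack(float(v)))
    buf.write(_U64.pack(int(record.len_raw_signal)))
    sig_blob = codecs.compress_signal(record.raw_signal, config.signal_method)
    buf.write(_U64.pack(len(sig_blob)))
    buf.write(sig_blob)
    for name, tag in header.aux_schema:
        _encode_aux(buf, record.aux_values.get(name, MISSING), tag)
    return codecs.compress_record_payload(buf.getvalue(), config.record_method)


def decode_record(
    payload: bytes, header: Slow5Header, config: CompressionConfig
) -> Slow5Record:
    """Inverse of :func:`encode_record`; needs only this frame's bytes."""
    raw = codecs.decompress_record_payload(payload, config.record_method)
    view = memoryview(raw)
    try:
        pos = 0
        (id_len,) = _U16.unpack_from(view, pos)
        pos += 2
        read_id = bytes(view[pos : pos + id_len]).decode("utf-8")
        pos += id_len
        (read_group,) = _U32.unpack_from(view, pos)
        pos += 4
        doubles = []
        for _ in range(4):
            (d,) = _F64.unpack_from(view, pos)
            doubles.append(d)
            pos += 8
        (len_raw,) = _U64.unpack_from(view, pos)
        pos += 8
        (sig_len,) = _U64.unpack_from(view, pos)
        pos += 8
        if pos + sig_len > len(raw):
            raise DecodeError("signal blob extends past record payload", offset=pos)
        signal = codecs.decompress_signal(bytes(view[pos : pos + sig_len]), config.signal_method)
        pos += sig_len
        aux_values: dict[str, Any] = {}
        for name, tag in header.aux_schema:
            aux_values[name], pos = _decode_aux(view, pos, tag)
        if pos != len(raw):
            raise DecodeError(f"{len(raw) - pos} trailing bytes in record payload", offset=pos)
    except struct.error as e:
        raise DecodeError(f"record payload truncated: {e}", offset=len(raw)) from e
    if signal.size != len_raw:
        raise DecodeError(
            f"record {read_id!r}: decoded {signal.size} samples, expected {len_raw}",
            offset=pos,
        )
    return Slow5Record(
        read_id=read_id,
        read_group=int(read_group),
        digitisation=doubles[0],
        offset=doubles[1],
        range=doubles[2],
        sampling_rate=doubles[3],
        len_raw_signal=int(len_raw),
        raw_signal=signal,
        aux_values=aux_values,
    )


# --------------------------------------------------------------------------
# Container writing
# --------------------------------------------------------------------------


@dataclass
class WriteSummary:
    records_written: int
    bytes_written: int


def write_blow5(
    header: Slow5Header,
    records: Iterable[Slow5Record],
    config: CompressionConfig,
    sink: str | Path | BinaryIO,
) -> WriteSummary:
    """Stream records into a BLOW5 container, one frame at a time.

    Enforces read_id uniqueness across the file.  Returns a summary of what
    was written.
    """
    header.validate()
    own = isinstance(sink, (str, Path))
    fh: BinaryIO = open(sink, "wb") if own else sink  # type: ignore[assignment]
    n = 0
    total = 0
    seen: set[str] = set()
    try:
        rec_byte, sig_byte = codecs.method_bytes(config)
        header_text = ascii_io.write_header(header).encode("utf-8")
        prelude = (
            MAGIC
            + bytes(LAYOUT_VERSION)
            + bytes((rec_byte, sig_byte))
            + _U32.pack(header.num_read_groups)
            + _U64.pack(len(header_text))
            + header_text
        )
        fh.write(prelude)
        total += len(prelude)
        for record in records:
            violations = validate_record(record, header)
            if violations:
                raise ValidationError(
                    f"record {record.read_id!r} is invalid: " + "; ".join(violations)
                )
            if record.read_id in seen:
                raise DuplicateReadIdError(f"duplicate read_id {record.read_id!r}")
            seen.add(record.read_id)
            payload = encode_record(record, header, config)
            fh.write(_U64.pack(len(payload)))
            fh.write(payload)
            total += 8 + len(payload)
            n += 1
        fh.write(EOF_SENTINEL)
        total += len(EOF_SENTINEL)
    finally:
        if own:
            fh.close()
    return WriteSummary(records_written=n, bytes_written=total)


# --------------------------------------------------------------------------
# Container reading
# --------------------------------------------------------------------------


@dataclass
class _Prelude:
    header: Slow5Header
    config: CompressionConfig
    data_start: int
    header_text: bytes


def read_prelude(fh: BinaryIO) -> _Prelude:
    """Parse the fixed prelude; leave ``fh`` at the first frame."""
    magic = fh.read(8)
    if magic[:5] != MAGIC[:5]:
        raise FormatError("not a BLOW5 file (bad magic)")
    version = fh.read(3)
    if len(version) != 3:
        raise TruncatedFileError("file ends inside the version field", offset=8)
    if version[0] > LAYOUT_VERSION[0]:
        raise FormatError(
            f"container layout major version {version[0]} is newer than supported "
            f"{LAYOUT_VERSION[0]}"
        )
    methods = fh.read(2)
    groups_raw = fh.read(4)
    hlen_raw = fh.read(8)
    if len(methods) != 2 or len(groups_raw) != 4 or len(hlen_raw) != 8:
        raise TruncatedFileError("file ends inside the prelude", offset=fh.tell())
    config = codecs.config_from_method_bytes(methods[0], methods[1])
    (hlen,) = _U64.unpack(hlen_raw)
    header_text = fh.read(hlen)
    if len(header_text) != hlen:
        raise TruncatedFileError("file ends inside the header block", offset=fh.tell())
    header = ascii_io.parse_header(io.StringIO(header_text.decode("utf-8")))
    (num_groups,) = _U32.unpack(groups_raw)
    if num_groups != header.num_read_groups:
        raise FormatError(
            f"prelude declares {num_groups} read groups but header text declares "
            f"{header.num_read_groups}"
        )
    return _Prelude(
        header=header, config=config, data_start=fh.tell(), header_text=header_text
    )


def iter_frames(fh: BinaryIO, start: int) -> Iterator[tuple[int, int, bytes]]:
    """Yield ``(frame_offset, frame_length, payload)`` until the sentinel.

    ``frame_length`` includes the 8-byte length prefix, matching what the
    index stores.
    """
    file_size = fh.seek(0, io.SEEK_END)
    fh.seek(start)
    last_good = start
    while True:
        head = fh.read(8)
        if head == EOF_SENTINEL:
            return
        if len(head) < 8:
            raise TruncatedFileError(
                "file ends without an end-of-file sentinel", offset=last_good
            )
        (plen,) = _U64.unpack(head)
        if last_good + 8 + plen > file_size:
            raise TruncatedFileError(
                f"frame at byte {last_good} declares {plen} payload bytes but only "
                f"{file_size - last_good - 8} remain",
                offset=last_good,
            )
        payload = fh.read(plen)
        if len(payload) != plen:
            raise TruncatedFileError(
                f"frame at byte {last_good} declares {plen} payload bytes but the "
                "file ends early",
                offset=last_good,
            )
        yield last_good, 8 + plen, payload
        last_good += 8 + plen


def read_blow5(
    source: str | Path | BinaryIO,
) -> tuple[Slow5Header, CompressionConfig, Iterator[Slow5Record]]:
    """Open a BLOW5 container; return header, compression config and a lazy
    record iterator (file order, one frame decoded at a time)."""
    own = isinstance(source, (str, Path))
    fh: BinaryIO = open(source, "rb") if own else source  # type: ignore[assignment]
    try:
        prelude = read_prelude(fh)
    except Exception:
        if own:
            fh.close()
        raise

    def _records() -> Iterator[Slow5Record]:
        try:
            for _, _, payload in iter_frames(fh, prelude.data_start):
                yield decode_record(payload, prelude.header, prelude.config)
        finally:
            if own:
                fh.close()

    return prelude.header, prelude.config, _records()


# --------------------------------------------------------------------------
# Conversion
# --------------------------------------------------------------------------


def detect_format(path: str | Path) -> str:
    """Sniff a file: returns ``"blow5"`` or ``"slow5"``."""
    with open(path, "rb") as fh:
        head = fh.read(5)
    return "blow5" if head == MAGIC[:5] else "slow5"


def open_any(
    path: str | Path,
) -> tuple[Slow5Header, CompressionConfig, Iterator[Slow5Record]]:
    """Open a SLOW5 or BLOW5 file uniformly (ASCII reports a none/none config)."""
    if detect_format(path) == "blow5":
        return read_blow5(path)
    header, records = ascii_io.read_slow5(path)
    return header, CompressionConfig(), records


def convert(
    source: str | Path,
    target: str | Path,
    encoding: str = "blow5",
    config: CompressionConfig | None = None,
) -> WriteSummary:
    """Convert between SLOW5 ASCII and BLOW5, preserving records exactly.

    ``encoding`` is ``"ascii"``/``"slow5"`` or ``"blow5"``; ``config`` applies
    to BLOW5 output only.
    """
    header, _, records = open_any(source)
    if encoding in ("ascii", "slow5"):
        n = ascii_io.write_slow5(target, header, records)
        return WriteSummary(records_written=n, bytes_written=Path(target).stat().st_size)
    if encoding == "blow5":
        return write_blow5(header, records, config or CompressionConfig(), target)
    raise ValueError(f"unknown target encoding {encoding!r}")
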