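"""Byte-offset index: read_id -> (offset, length), for parallel random access.

The index is what turns a SLOW5/BLOW5 file into a random-access store: it is
loaded into a hash map keyed by read identifier, and each lookup yields the
byte offset and byte length of one record.  Fetches then use ``os.pread``,
which takes an explicit offset and never moves a shared file position, so any
number of threads can read through one open file descriptor with no locking —
results are independent of worker count and scheduling.

Index file layout (little-endian)::

    magic      b"S5IDX" + version byte 0x01
    data_size  u64   size of the indexed data file at build time
    header_id  8 bytes  blake2b-8 digest of the data file's header block
    entries    per record: u16 id length || id bytes || u64 offset || u64 length
    count      u64   trailing entry count

For ASCII data files the offset/length cover the record's line without its
terminator; for BLOW5 they cover the whole frame including its 8-byte length
prefix.  ``data_size`` and ``header_id`` give cheap staleness detection when
the data file is regenerated.  Discovery convention: ``<data path>.idx``.
"""

from __future__ import annotations

import hashlib
import io
import os
import struct
from pathlib import Path
from typing import Iterator

import numpy as np

from . import ascii_io, binary_io
from .model import (
    CompressionConfig,
    DecodeError,
    DuplicateReadIdError,
    FormatError,
    IndexEntry,
    ReadNotFoundError,
    Slow5Header,
    Slow5Record,
    StaleIndexError,
)

INDEX_MAGIC = b"S5IDX\x01"
INDEX_SUFFIX = ".idx"

_U16 = struct.Struct("<H")
_U64 = struct.Struct("<Q")


def default_index_path(data_path: str | Path) -> Path:
    return Path(str(data_path) + INDEX_SUFFIX)


def _header_digest(header_bytes: bytes) -> bytes:
    return hashlib.blake2b(header_bytes, digest_size=8).digest()


def _scan_ascii(path: Path) -> tuple[bytes, Iterator[tuple[str, int, int]]]:
    """Return (header bytes, iterator of (read_id, offset, length)) for ASCII."""
    fh = open(path, "rb")
    header_buf = bytearray()
    data_start = 0
    while True:
        pos = fh.tell()
        line = fh.readline()
        if not line:
            data_start = pos
            break
        if line.startswith(b"#") or line.startswith(b"@"):
            header_buf += line
        else:
            data_start = pos
            break

    def _entries() -> Iterator[tuple[str, int, int]]:
        try:
            fh.seek(data_start)
            while True:
                off = fh.tell()
                line = fh.readline()
                if not line:
                    return
                stripped = line.rstrip(b"\r\n")
                if not stripped:
                    continue
                read_id = stripped.split(b"\t", 1)[0].decode("utf-8")
                yield read_id, off, len(stripped)
        finally:
            fh.close()

    return bytes(header_buf), _entries()


def _scan_blow5(path: Path) -> tuple[bytes, Iterator[tuple[str, int, int]]]:
    fh = open(path, "rb")
    prelude = binary_io.read_prelude(fh)

    def _entries() -> Iterator[tuple[str, int, int]]:
        try:
            for off, length, payload in binary_io.iter_frames(fh, prelude.data_start):
                record = binary_io.decode_record(payload, prelude.header, prelude.config)
                yield record.read_id, off, length
        finally:
            fh.close()

    return prelude.header_text, _entries()


def build_index(
    data_path: str | Path, index_path: str | Path | None = None
) -> Path:
    """Scan a SLOW5/BLOW5 file and write its index; return the index path.

    Raises :class:`DuplicateReadIdError` if a read_id occurs twice.
    """
    data_path = Path(data_path)
    index_path = Path(index_path) if index_path else default_index_path(data_path)
    if binary_io.detect_format(data_path) == "blow5":
        header_bytes, entries = _scan_blow5(data_path)
    else:
        header_bytes, entries = _scan_ascii(data_path)
    seen: set[str] = set()
    count = 0
    with open(index_path, "wb") as out:
        out.write(INDEX_MAGIC)
        out.write(_U64.pack(data_path.stat().st_size))
        out.write(_header_digest(header_bytes))
        for read_id, off, length in entries:
            if read_id in seen:
                raise DuplicateReadIdError(f"duplicate read_id {read_id!r}")
            seen.add(read_id)
            rid = read_id.encode("utf-8")
            out.write(_U16.pack(len(rid)))
            out.write(rid)
            out.write(_U64.pack(off))
            out.write(_U64.pack(length))
            count += 1
        out.write(_U64.pack(count))
    return index_path


def load_index(
    index_path: str | Path, data_path: str | Path | None = None
) -> dict[str, IndexEntry]:
    """Load an index file into a read_id -> :class:`IndexEntry` hash map.

    If ``data_path`` is given (or derivable by stripping the ``.idx`` suffix
    and the file exists), the stored size and header digest are checked and a
    :class:`StaleIndexError` is raised on mismatch.
    """
    index_path = Path(index_path)
    blob = index_path.read_bytes()
    if not blob.startswith(INDEX_MAGIC[:5]):
        raise FormatError(f"{index_path} is not a SLOW5 index file")
    if blob[5] > INDEX_MAGIC[5]:
        raise FormatError(f"index version {blob[5]} is newer than supported")
    if len(blob) < 6 + 8 + 8 + 8:
        raise DecodeError("index file truncated", offset=len(blob))
    (stored_size,) = _U64.unpack_from(blob, 6)
    stored_digest = blob[14:22]

    if data_path is None:
        candidate = Path(str(index_path)[: -len(INDEX_SUFFIX)]) if str(index_path).endswith(INDEX_SUFFIX) else None
        data_path = candidate if candidate and candidate.exists() else None
    if data_path is not None:
        data_path = Path(data_path)
        if data_path.stat().st_size != stored_size:
            raise StaleIndexError(
                f"index {index_path} was built for a {stored_size}-byte file; "
                f"{data_path} is {data_path.stat().st_size} bytes"
            )
        if binary_io.detect_format(data_path) == "blow5":
            with open(data_path, "rb") as fh:
                header_bytes = binary_io.read_prelude(fh).header_text
        else:
            header_bytes, _ = _scan_ascii(data_path)
        if _header_digest(header_bytes) != stored_digest:
            raise StaleIndexError(f"index {index_path} does not match {data_path}'s header")

    (count,) = _U64.unpack_from(blob, len(blob) - 8)
    entries: dict[str, IndexEntry] = {}
    pos = 22
    end = len(blob) - 8
    while pos < end:
        (id_len,) = _U16.unpack_from(blob, pos)
        pos += 2
        rid = blob[pos : pos + id_len].decode("utf-8")
        pos += id_len
        (off,) = _U64.unpack_from(blob, pos)
        (length,) = _U64.unpack_from(blob, pos + 8)
        pos += 16
        entries[rid] = IndexEntry(read_id=rid, offset=off, length=length)
    if len(entries) != count:
        raise DecodeError(
            f"index declares {count} entries but {len(entries)} were read", offset=end
        )
    return entries


class RandomAccessReader:
    """Random access to a SLOW5/BLOW5 file through its index.

    Opens the data file once and serves every ``get`` with ``os.pread`` at the
    indexed offset, so concurrent calls from any number of threads share the
    single file descriptor without locking.  Builds the index on first use if
    ``<path>.idx`` does not exist.
    """

    def __init__(
        self,
        data_path: str | Path,
        index_path: str | Path | None = None,
        index_map: dict[str, IndexEntry] | None = None,
    ):
        self.data_path = Path(data_path)
        self.format = binary_io.detect_format(self.data_path)
        if self.format == "blow5":
            with open(self.data_path, "rb") as fh:
                prelude = binary_io.read_prelude(fh)
            self.header: Slow5Header = prelude.header
            self.config: CompressionConfig = prelude.config
        else:
            with open(self.data_path, "r", encoding="utf-8", newline="") as fh:
                self.header = ascii_io.parse_header(fh)
            self.config = CompressionConfig()
        if index_map is not None:
            self.index = index_map
        else:
            idx = Path(index_path) if index_path else default_index_path(self.data_path)
            if not idx.exists():
                build_index(self.data_path, idx)
            self.index = load_index(idx, self.data_path)
        self._fd = os.open(self.data_path, os.O_RDONLY)

    # -- mapping-ish surface -------------------------------------------------

    @property
    def read_ids(self) -> list[str]:
        return list(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.index

    def get(self, read_id: str) -> Slow5Record:
        """Fetch and decode one record; thread-safe, lock-free."""
        try:
            entry = self.index[read_id]
        except KeyError:
            raise ReadNotFoundError(read_id) from None
        buf = os.pread(self._fd, entry.length, entry.offset)
        if len(buf) != entry.length:
            raise DecodeError(
                f"short read for {read_id!r}: got {len(buf)} of {entry.length} bytes",
                offset=entry.offset,
            )
        if self.format == "blow5":
            (plen,) = _U64.unpack_from(buf, 0)
            if plen != entry.length - 8:
                raise DecodeError(
                    f"frame for {read_id!r} declares {plen} payload bytes but the "
                    f"index recorded {entry.length - 8}",
                    offset=entry.offset,
                )
            return binary_io.decode_record(buf[8:], self.header, self.config)
        return ascii_io.parse_record(buf.decode("utf-8"), self.header)

    __getitem__ = get

    def close(self) -> None:
        if self._fd is not None:
            os.close(self._fd)
            self._fd = None  # type: ignore[assignment]

    def __enter__(self) -> "RandomAccessReader":
        return self

    def __exit__(self, *exc: object) -> None:
        self.close()


def get_read(
    data_file: str | Path | RandomAccessReader,
    index_map: dict[str, IndexEntry] | None,
    read_id: str,
) -> Slow5Record:
    """Fetch one record by id.

    ``data_file`` may be an open :class:`RandomAccessReader` (preferred for
    repeated or concurrent access) or a path, in which case a reader is opened
    around ``index_map`` for this single call.
    """
    if isinstance(data_file, RandomAccessReader):
        return data_file.get(read_id)
    with RandomAccessReader(data_file, index_map=index_map) as reader:
        return reader.get(read_id)
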