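"""Per-record and signal compression codecs.

Two orthogonal layers:

* **signal codec** (``svb``): the raw 16-bit signal is delta-encoded
  (successive differences, wrapping modulo 2^16 so the transform is total
  over all int16 inputs), zig-zag mapped to unsigned 16-bit, then packed with
  a StreamVByte/Group-Varint scheme specialised to two widths — one control
  bit per value selects a 1- or 2-byte little-endian payload.  Control bits
  are packed LSB-first; the value count is stored explicitly.

* **record compression** (``zlib`` / ``zstd``): the serialised record bytes
  are compressed as one independent stream per record, so any record can be
  decompressed without touching any other — the property that makes indexed
  parallel access possible.

``zstd`` over ``svb`` is the "vbz" preset.  Nanopore current is locally
smooth, so deltas are small and mostly fit one byte; that is the entire
compression argument.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass

import numpy as np
from numcodecs import Zstd

from .model import (
    CompressionConfig,
    DecodeError,
    RecordCompression,
    SignalCompression,
    UnsupportedCompressionError,
)

#: zstd level 1: speed-oriented, matching the format's parallel-access goal.
ZSTD_LEVEL = 1
#: zlib default level.
ZLIB_LEVEL = 6

_zstd = Zstd(level=ZSTD_LEVEL)


# --------------------------------------------------------------------------
# Delta
# --------------------------------------------------------------------------


def delta_encode(signal: np.ndarray) -> np.ndarray:
    """First-order differences with int16 wrap-around; d[0] is s[0] itself.

    Differences are taken modulo 2^16 (int16 overflow wraps), which keeps
    every delta representable in 16 bits and makes the transform exactly
    invertible for any int16 input.
    """
    s = np.asarray(signal, dtype=np.int16)
    if s.size == 0:
        return s.copy()
    d = np.empty_like(s)
    d[0] = s[0]
    np.subtract(s[1:], s[:-1], out=d[1:])  # int16 arithmetic wraps mod 2^16
    return d


def delta_decode(deltas: np.ndarray) -> np.ndarray:
    """Inverse of :func:`delta_encode` (cumulative sum modulo 2^16)."""
    d = np.asarray(deltas, dtype=np.int16)
    if d.size == 0:
        return d.copy()
    return np.cumsum(d.astype(np.uint16), dtype=np.uint16).astype(np.int16)


# --------------------------------------------------------------------------
# Zig-zag
# --------------------------------------------------------------------------


def zigzag_encode(values: np.ndarray | int, bits: int = 16) -> np.ndarray | int:
    """Map signed integers to unsigned: 0,-1,1,-2,... -> 0,1,2,3,...

    ``bits`` is the width of the signed input; the result fits the same
    number of unsigned bits.  Accepts a scalar or an array.
    """
    scalar = np.isscalar(values)
    v = np.asarray(values, dtype=np.int64)
    lo, hi = -(1 << (bits - 1)), (1 << (bits - 1)) - 1
    if v.size and (v.min() < lo or v.max() > hi):
        raise OverflowError(f"value outside signed {bits}-bit range")
    z = (v << 1) ^ (v >> 63)  # arithmetic shift propagates the sign
    z = z.astype(np.uint64)
    return int(z[()]) if scalar else z


def zigzag_decode(values: np.ndarray | int, bits: int = 16) -> np.ndarray | int:
    """Inverse of :func:`zigzag_encode`."""
    scalar = np.isscalar(values)
    z = np.asarray(values, dtype=np.uint64)
    if z.size and int(z.max()) >= (1 << bits):
        raise OverflowError(f"value outside unsigned {bits}-bit range")
    v = (z >> np.uint64(1)).astype(np.int64) ^ -(z & np.uint64(1)).astype(np.int64)
    return int(v[()]) if scalar else v


# --------------------------------------------------------------------------
# StreamVByte (two-width variant)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SvbBlock:
    """A StreamVByte-encoded block: explicit count, control bits, data bytes.

    Control bit *i* (bit ``i % 8`` of control byte ``i // 8``, LSB-first) is
    0 when value *i* occupies one data byte and 1 when it occupies two
    (little-endian).  Encoded size is therefore
    ``ceil(n/8) + n + popcount(control)``.
    """

    count: int
    control: bytes
    data: bytes


def svb_encode(values: np.ndarray) -> SvbBlock:
    """Encode unsigned 16-bit values into control and data streams."""
    v = np.asarray(values, dtype=np.uint64)
    if v.size and int(v.max()) > 0xFFFF:
        raise OverflowError("svb value does not fit 16 bits")
    v = v.astype(np.uint16)
    n = v.size
    wide = v >= 256  # control bit per value
    control = np.packbits(wide, bitorder="little").tobytes()
    pairs = v.astype("<u2").view(np.uint8).reshape(-1, 2) if n else np.empty((0, 2), np.uint8)
    keep = np.ones((n, 2), dtype=bool)
    keep[:, 1] = wide
    data = pairs[keep].tobytes()
    return SvbBlock(count=n, control=control, data=data)


def svb_decode(block: SvbBlock) -> np.ndarray:
    """Decode a block back to its uint16 values."""
    n = block.count
    if n == 0:
        if block.control or block.data:
            raise DecodeError("svb block with count 0 has trailing bytes", offset=0)
        return np.array([], dtype=np.uint16)
    expected_control = (n + 7) // 8
    if len(block.control) != expected_control:
        raise DecodeError(
            f"svb control stream has {len(block.control)} bytes, expected {expected_control}",
            offset=0,
        )
    bits = np.unpackbits(
        np.frombuffer(block.control, dtype=np.uint8), bitorder="little"
    )[:n].astype(np.int64)
    widths = 1 + bits
    expected_data = int(widths.sum())
    if len(block.data) != expected_data:
        raise DecodeError(
            f"svb data stream has {len(block.data)} bytes, expected {expected_data}",
            offset=len(block.control),
        )
    starts = np.zeros(n, dtype=np.int64)
    np.cumsum(widths[:-1], out=starts[1:])
    data = np.frombuffer(block.data + b"\x00", dtype=np.uint8)  # pad for safe hi index
    lo = data[starts].astype(np.uint16)
    hi = np.where(bits == 1, data[starts + 1], 0).astype(np.uint16)
    return lo | (hi << 8)


def svb_encoded_size(block: SvbBlock) -> int:
    """Byte size of the control + data streams (excluding the stored count)."""
    return len(block.control) + len(block.data)


# --------------------------------------------------------------------------
# Signal-level framing
# --------------------------------------------------------------------------

_COUNT = struct.Struct("<Q")


def compress_signal(
    signal: np.ndarray, method: SignalCompression = SignalCompression.SVB
) -> bytes:
    """Serialise a signal: raw little-endian int16, or delta+zigzag+svb.

    The svb payload is ``count (u64 LE) || control bytes || data bytes``.
    """
    method = SignalCompression(method)
    s = np.asarray(signal, dtype=np.int16)
    if method is SignalCompression.NONE:
        return s.astype("<i2").tobytes()
    block = svb_encode(zigzag_encode(delta_encode(s).astype(np.int64), bits=16))
    return _COUNT.pack(block.count) + block.control + block.data


def decompress_signal(
    payload: bytes, method: SignalCompression = SignalCompression.SVB
) -> np.ndarray:
    """Exact inverse of :func:`compress_signal`."""
    method = SignalCompression(method)
    if method is SignalCompression.NONE:
        if len(payload) % 2:
            raise DecodeError("raw int16 payload has odd length", offset=len(payload))
        return np.frombuffer(payload, dtype="<i2").astype(np.int16)
    if len(payload) < _COUNT.size:
        raise DecodeError("svb payload shorter than its count field", offset=0)
    (n,) = _COUNT.unpack_from(payload, 0)
    n_control = (n + 7) // 8
    control_end = _COUNT.size + n_control
    if len(payload) < control_end:
        raise DecodeError("svb payload truncated inside control stream", offset=len(payload))
    block = SvbBlock(
        count=n, control=payload[_COUNT.size : control_end], data=payload[control_end:]
    )
    z = svb_decode(block)
    return delta_decode(zigzag_decode(z.astype(np.uint64), bits=16).astype(np.int16))


# --------------------------------------------------------------------------
# Record-level compression
# --------------------------------------------------------------------------


def compress_record_payload(
    payload: bytes, method: RecordCompression = RecordCompression.ZSTD
) -> bytes:
    """Compress one record's serialised bytes as an independent stream."""
    method = RecordCompression(method)
    if method is RecordCompression.NONE:
        return bytes(payload)
    if not payload:
        return b""  # an empty stream decodes to empty, for every method
    if method is RecordCompression.ZLIB:
        return zlib.compress(payload, ZLIB_LEVEL)
    return bytes(_zstd.encode(bytes(payload)))


def decompress_record_payload(
    payload: bytes, method: RecordCompression = RecordCompression.ZSTD
) -> bytes:
    """Inverse of :func:`compress_record_payload`; needs no other record's bytes."""
    method = RecordCompression(method)
    if method is RecordCompression.NONE:
        return bytes(payload)
    if not payload:
        return b""
    try:
        if method is RecordCompression.ZLIB:
            return zlib.decompress(payload)
        return bytes(_zstd.decode(bytes(payload)))
    except Exception as e:
        raise DecodeError(f"corrupt {method.value} record stream: {e}", offset=0) from e


def method_bytes(config: CompressionConfig) -> tuple[int, int]:
    """(record_method, signal_method) as container method bytes."""
    rec = {RecordCompression.NONE: 0, RecordCompression.ZLIB: 1, RecordCompression.ZSTD: 2}
    sig = {SignalCompression.NONE: 0, SignalCompression.SVB: 1}
    return rec[config.record_method], sig[config.signal_method]


def config_from_method_bytes(record_byte: int, signal_byte: int) -> CompressionConfig:
    rec = {0: RecordCompression.NONE, 1: RecordCompression.ZLIB, 2: RecordCompression.ZSTD}
    sig = {0: SignalCompression.NONE, 1: SignalCompression.SVB}
    if record_byte not in rec:
        raise UnsupportedCompressionError(f"unknown record compression byte {record_byte}")
    if signal_byte not in sig:
        raise UnsupportedCompressionError(f"unknown signal compression byte {signal_byte}")
    return CompressionConfig(rec[record_byte], sig[signal_byte])
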