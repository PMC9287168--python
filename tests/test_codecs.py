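"""Signal codec pipeline (delta, zig-zag, StreamVByte) and record compression.

The StreamVByte tests check the vectorised codec against a deliberately naive
one-value-at-a-time reference implementation written here, independent of the
package's code paths.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slow5kit import codecs
from slow5kit.codecs import SvbBlock
from slow5kit.model import (
    CompressionConfig,
    DecodeError,
    RecordCompression,
    SignalCompression,
    UnsupportedCompressionError,
)

# --------------------------------------------------------------------------
# Naive reference codec (the oracle): one value at a time, no numpy tricks.
# --------------------------------------------------------------------------


def naive_svb_encode(values):
    control_bits = []
    data = bytearray()
    for v in values:
        v = int(v)
        assert 0 <= v < 1 << 16
        if v < 256:
            control_bits.append(0)
            data.append(v)
        else:
            control_bits.append(1)
            data.append(v & 0xFF)
            data.append(v >> 8)
    control = bytearray((len(values) + 7) // 8)
    for i, bit in enumerate(control_bits):
        if bit:
            control[i // 8] |= 1 << (i % 8)  # LSB-first
    return bytes(control), bytes(data)


def naive_svb_decode(count, control, data):
    out = []
    pos = 0
    for i in range(count):
        bit = (control[i // 8] >> (i % 8)) & 1
        if bit:
            out.append(data[pos] | (data[pos + 1] << 8))
            pos += 2
        else:
            out.append(data[pos])
            pos += 1
    assert pos == len(data)
    return out


# --------------------------------------------------------------------------
# Delta
# --------------------------------------------------------------------------


class TestDelta:
    def test_empty(self):
        assert codecs.delta_encode(np.array([], dtype=np.int16)).size == 0

    def test_worked_example_prefix(self):
        assert codecs.delta_encode(np.array([498, 492], np.int16)).tolist() == [498, -6]

    def test_constant_series(self):
        assert codecs.delta_encode(np.array([5, 5, 5], np.int16)).tolist() == [5, 0, 0]

    def test_extreme_jump_wraps_and_round_trips(self):
        """int16 wrap-around keeps the transform total and invertible."""
        s = np.array([-32768, 32767, -32768, 0], dtype=np.int16)
        assert np.array_equal(codecs.delta_decode(codecs.delta_encode(s)), s)

    @given(st.lists(st.integers(-32768, 32767), max_size=300))
    def test_round_trip(self, xs):
        s = np.array(xs, dtype=np.int16)
        assert np.array_equal(codecs.delta_decode(codecs.delta_encode(s)), s)


# --------------------------------------------------------------------------
# Zig-zag
# --------------------------------------------------------------------------


class TestZigzag:
    @pytest.mark.parametrize("v, z", [(0, 0), (-1, 1), (1, 2), (-6, 11), (498, 996)])
    def test_closed_form(self, v, z):
        assert codecs.zigzag_encode(v) == z
        assert codecs.zigzag_decode(z) == v

    def test_exhaustive_16_bit_identity(self):
        """Round trip over all 65,536 signed 16-bit values."""
        v = np.arange(-32768, 32768, dtype=np.int64)
        z = codecs.zigzag_encode(v)
        assert int(z.max()) <= 0xFFFF
        assert np.array_equal(codecs.zigzag_decode(z), v)
        # closed form: non-negative v -> 2v, negative v -> -2v - 1
        expected = np.where(v >= 0, 2 * v, -2 * v - 1)
        assert np.array_equal(z.astype(np.int64), expected)

    def test_overflow_is_a_width_error(self):
        with pytest.raises(OverflowError):
            codecs.zigzag_encode(40000, bits=16)
        with pytest.raises(OverflowError):
            codecs.zigzag_decode(1 << 16, bits=16)


# --------------------------------------------------------------------------
# StreamVByte
# --------------------------------------------------------------------------


class TestSvb:
    def test_empty_block(self):
        block = codecs.svb_encode(np.array([], dtype=np.uint16))
        assert block.count == 0 and block.control == b"" and block.data == b""
        assert codecs.svb_decode(block).size == 0

    def test_hand_computed_layout(self):
        """[1, 300]: control byte 0b00000010; data 0x01, then 0x2C 0x01."""
        block = codecs.svb_encode(np.array([1, 300], dtype=np.uint16))
        assert block.control == bytes([0b00000010])
        assert block.data == bytes([0x01, 0x2C, 0x01])
        control, data = naive_svb_encode([1, 300])
        assert (block.control, block.data) == (control, data)

    def test_width_error(self):
        with pytest.raises(OverflowError):
            codecs.svb_encode(np.array([1 << 16], dtype=np.uint64))

    @given(st.lists(st.integers(0, 0xFFFF), max_size=400))
    def test_matches_naive_oracle(self, xs):
        block = codecs.svb_encode(np.array(xs, dtype=np.uint16))
        control, data = naive_svb_encode(xs)
        assert block.control == control and block.data == data
        assert codecs.svb_decode(block).tolist() == naive_svb_decode(
            block.count, block.control, block.data
        )

    @given(st.lists(st.integers(0, 0xFFFF), max_size=400))
    def test_size_formula(self, xs):
        """encoded size == ceil(n/8) + n + popcount(control), always."""
        block = codecs.svb_encode(np.array(xs, dtype=np.uint16))
        n = len(xs)
        popcount = sum(bin(b).count("1") for b in block.control)
        assert codecs.svb_encoded_size(block) == (n + 7) // 8 + n + popcount

    def test_corrupt_streams_are_decode_errors(self):
        block = codecs.svb_encode(np.array([1, 300], dtype=np.uint16))
        with pytest.raises(DecodeError):
            codecs.svb_decode(SvbBlock(block.count, b"", block.data))
        with pytest.raises(DecodeError):
            codecs.svb_decode(SvbBlock(block.count, block.control, block.data[:-1]))


# --------------------------------------------------------------------------
# Signal-level framing
# --------------------------------------------------------------------------


class TestCompressSignal:
    def test_empty_signal_svb_is_header_only(self):
        payload = codecs.compress_signal(np.array([], np.int16), SignalCompression.SVB)
        assert payload == b"\x00" * 8
        assert codecs.decompress_signal(payload, SignalCompression.SVB).size == 0

    def test_constant_signal_forced_chain(self):
        """Constant 100 x 8: deltas [100,0x7], zigzag [200,0x7], all 1-byte."""
        s = np.full(8, 100, dtype=np.int16)
        payload = codecs.compress_signal(s, SignalCompression.SVB)
        count, control, data = payload[:8], payload[8:9], payload[9:]
        assert int.from_bytes(count, "little") == 8
        assert control == b"\x00"  # every value fits one byte
        assert data == bytes([0xC8]) + b"\x00" * 7
        assert np.array_equal(codecs.decompress_signal(payload, "svb"), s)

    @given(st.lists(st.integers(-32768, 32767), max_size=500))
    @pytest.mark.parametrize("method", list(SignalCompression))
    def test_round_trip_both_methods(self, method, xs):
        s = np.array(xs, dtype=np.int16)
        back = codecs.decompress_signal(codecs.compress_signal(s, method), method)
        assert back.dtype == np.int16 and np.array_equal(back, s)

    def test_truncated_payload_reports_position(self):
        payload = codecs.compress_signal(np.arange(100, dtype=np.int16), "svb")
        with pytest.raises(DecodeError):
            codecs.decompress_signal(payload[:4], "svb")
        with pytest.raises(DecodeError):
            codecs.decompress_signal(payload[:-3], "svb")


# --------------------------------------------------------------------------
# Record-level compression
# --------------------------------------------------------------------------


class TestRecordCompression:
    def test_empty_payload_none(self):
        assert codecs.compress_record_payload(b"", RecordCompression.NONE) == b""

    @given(payload=st.binary(max_size=2000))
    @pytest.mark.parametrize("method", list(RecordCompression))
    def test_round_trip(self, method, payload):
        out = codecs.compress_record_payload(payload, method)
        assert codecs.decompress_record_payload(out, method) == payload

    @pytest.mark.parametrize(
        "method", [RecordCompression.ZLIB, RecordCompression.ZSTD]
    )
    def test_streams_are_independent(self, method):
        """The second record's stream decodes alone, with no bytes from the first."""
        first = codecs.compress_record_payload(b"a" * 500, method)
        second = codecs.compress_record_payload(b"b" * 500, method)
        assert codecs.decompress_record_payload(second, method) == b"b" * 500
        del first

    @pytest.mark.parametrize(
        "method", [RecordCompression.ZLIB, RecordCompression.ZSTD]
    )
    def test_truncated_stream_is_a_decode_error(self, method):
        out = codecs.compress_record_payload(b"hello world" * 20, method)
        with pytest.raises(DecodeError):
            codecs.decompress_record_payload(out[: len(out) // 2], method)


def test_unknown_method_bytes_rejected():
    with pytest.raises(UnsupportedCompressionError):
        codecs.config_from_method_bytes(9, 0)
    with pytest.raises(UnsupportedCompressionError):
        codecs.config_from_method_bytes(0, 9)


def test_method_bytes_round_trip():
    from slow5kit.model import ALL_CONFIGS

    for cfg in ALL_CONFIGS:
        assert codecs.config_from_method_bytes(*codecs.method_bytes(cfg)) == cfg


def test_vbz_not_larger_than_zlib_on_random_walks():
    """Directional size ordering on locally smooth synthetic signals."""
    rng = np.random.default_rng(42)
    vbz_total = zlib_total = 0
    for _ in range(50):
        steps = np.round(rng.normal(0, 5, size=1500)).astype(np.int64)
        steps[0] = 500
        sig = np.clip(np.cumsum(steps), -32768, 32767).astype(np.int16)
        raw = codecs.compress_signal(sig, SignalCompression.NONE)
        svb = codecs.compress_signal(sig, SignalCompression.SVB)
        vbz_total += len(codecs.compress_record_payload(svb, RecordCompression.ZSTD))
        zlib_total += len(codecs.compress_record_payload(raw, RecordCompression.ZLIB))
    assert vbz_total <= zlib_total
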