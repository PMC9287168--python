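"""merge/split/stats algebra, FAST5 conversion, and CLI parity."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from slow5kit import ascii_io, binary_io, fixtures, tools
from slow5kit.cli import main as cli_main
from slow5kit.model import (
    CompressionConfig,
    DuplicateReadIdError,
    SchemaError,
    UnsupportedFormatError,
)


def _write(tmp_path, name, n=5, seed=0, **kw):
    header, records = fixtures.generate_records(n, mean_length=100, seed=seed, **kw)
    path = tmp_path / name
    ascii_io.write_slow5(path, header, records)
    return path, header, records


class TestMerge:
    def test_single_input_is_content_equal_copy(self, tmp_path):
        path, header, records = _write(tmp_path, "a.slow5")
        out = tmp_path / "m.slow5"
        tools.merge([path], out)
        header2, stream = ascii_io.read_slow5(out)
        assert header2 == header and list(stream) == records

    def test_distinct_groups_are_remapped(self, tmp_path):
        p1, h1, r1 = _write(tmp_path, "a.slow5", seed=1)
        p2, h2, r2 = _write(tmp_path, "b.slow5", seed=2)
        out = tmp_path / "m.slow5"
        merged = tools.merge([p1, p2], out)
        assert merged.num_read_groups == 2
        _, stream = ascii_io.read_slow5(out)
        records = list(stream)
        groups = {r.read_id: r.read_group for r in records}
        assert all(groups[r.read_id] == 0 for r in r1)
        assert all(groups[r.read_id] == 1 for r in r2)
        # content otherwise unchanged
        assert [r.copy(read_group=0) for r in records[len(r1):]] == [
            r.copy(read_group=0) for r in r2
        ]

    def test_identical_attribute_maps_collapse(self, tmp_path):
        p1, header, r1 = _write(tmp_path, "a.slow5", seed=3)
        h2, r2 = fixtures.generate_records(5, mean_length=100, seed=4)
        p2 = tmp_path / "b.slow5"
        # same attribute map as file 1, different reads
        ascii_io.write_slow5(p2, header, [r.copy(read_id=r.read_id + "-b") for r in r2])
        merged = tools.merge([p1, p2], tmp_path / "m.slow5")
        assert merged.num_read_groups == 1

    def test_duplicate_read_id_across_inputs(self, tmp_path):
        p1, header, r1 = _write(tmp_path, "a.slow5", seed=5)
        p2 = tmp_path / "b.slow5"
        ascii_io.write_slow5(p2, header, r1)  # same ids
        with pytest.raises(DuplicateReadIdError):
            tools.merge([p1, p2], tmp_path / "m.slow5")

    def test_conflicting_version_majors(self, tmp_path):
        p1, h1, r1 = _write(tmp_path, "a.slow5", seed=6)
        h2, r2 = fixtures.generate_records(3, mean_length=100, seed=7)
        h2.slow5_version = "2.0.0"
        p2 = tmp_path / "b.slow5"
        ascii_io.write_slow5(p2, h2, r2)
        with pytest.raises(SchemaError, match="major"):
            tools.merge([p1, p2], tmp_path / "m.slow5")


class TestSplit:
    def test_by_group_counts(self, tmp_path):
        header, records = fixtures.generate_records(
            5, num_read_groups=2, mean_length=80, seed=8
        )
        path = tmp_path / "two.slow5"
        ascii_io.write_slow5(path, header, records)
        parts = tools.split_by_group(path, tmp_path / "parts")
        assert len(parts) == 2
        sizes = []
        for part in parts:
            h, stream = ascii_io.read_slow5(part)
            recs = list(stream)
            assert h.num_read_groups == 1
            assert all(r.read_group == 0 for r in recs)
            sizes.append(len(recs))
        assert sorted(sizes) == [2, 3]

    def test_by_reads_chunking(self, tmp_path):
        path, header, records = _write(tmp_path, "five.slow5", n=5, seed=9)
        parts = tools.split_by_reads(path, tmp_path / "parts", 2)
        counts = [len(list(ascii_io.read_slow5(p)[1])) for p in parts]
        assert counts == [2, 2, 1]

    def test_split_then_merge_is_content_equal(self, tmp_path):
        header, records = fixtures.generate_records(
            7, num_read_groups=3, mean_length=60, seed=10
        )
        path = tmp_path / "orig.slow5"
        ascii_io.write_slow5(path, header, records)
        parts = tools.split_by_group(path, tmp_path / "parts")
        merged_path = tmp_path / "merged.slow5"
        merged = tools.merge(parts, merged_path)
        assert merged.num_read_groups == header.num_read_groups
        _, stream = ascii_io.read_slow5(merged_path)
        assert sorted(stream, key=lambda r: r.read_id) == sorted(
            records, key=lambda r: r.read_id
        )

    def test_signal_checksum_preserved_through_split_merge(self, tmp_path):
        header, records = fixtures.generate_records(
            6, num_read_groups=2, mean_length=90, seed=12
        )
        path = tmp_path / "orig.slow5"
        ascii_io.write_slow5(path, header, records)
        before = tools.signal_checksum(records)
        parts = tools.split_by_reads(path, tmp_path / "parts", 2)
        tools.merge(parts, tmp_path / "m.blow5", CompressionConfig.vbz())
        after = tools.signal_checksum(binary_io.read_blow5(tmp_path / "m.blow5")[2])
        assert before == after


class TestStats:
    def test_header_only_file(self, tmp_path):
        from slow5kit.model import Slow5Header

        path = tmp_path / "empty.slow5"
        ascii_io.write_slow5(path, Slow5Header(), [])
        assert tools.stats(path)["record_count"] == 0

    def test_worked_example_counts(self, table1, tmp_path):
        header, records = table1
        path = tmp_path / "t1.slow5"
        ascii_io.write_slow5(path, header, records)
        s = tools.stats(path)
        assert s["record_count"] == 3
        assert s["num_read_groups"] == 1
        assert s["total_signal_samples"] == 123456 + 2000 + 3000

    def test_ascii_vs_vbz_same_records_fewer_bytes(self, small_slow5, small_blow5):
        a, b = tools.stats(small_slow5), tools.stats(small_blow5)
        assert a["record_count"] == b["record_count"]
        assert a["total_signal_samples"] == b["total_signal_samples"]
        assert b["file_bytes"] < a["file_bytes"]


class TestFast5Conversion:
    def test_fixture_round_trip(self, tmp_path):
        header, records = fixtures.generate_records(3, mean_length=150, seed=13)
        f5 = fixtures.generate_fast5_fixture(header, records, tmp_path / "x.fast5")
        (out,) = tools.f2s([f5], tmp_path / "out")
        _, _, stream = binary_io.read_blow5(out)
        got = sorted(stream, key=lambda r: r.read_id)
        want = sorted(records, key=lambda r: r.read_id)
        assert [r.read_id for r in got] == [r.read_id for r in want]
        for g, w in zip(got, want):
            assert np.array_equal(g.raw_signal, w.raw_signal)
            assert g.digitisation == w.digitisation and g.offset == w.offset

    def test_worker_count_does_not_change_results(self, tmp_path):
        paths = []
        for i in range(8):
            header, records = fixtures.generate_records(2, mean_length=60, seed=100 + i)
            paths.append(
                fixtures.generate_fast5_fixture(header, records, tmp_path / f"{i}.fast5")
            )
        out1 = tools.f2s(paths, tmp_path / "w1", workers=1)
        out4 = tools.f2s(paths, tmp_path / "w4", workers=4)

        def merged_set(outs):
            return sorted(
                (r for p in outs for r in binary_io.read_blow5(p)[2]),
                key=lambda r: r.read_id,
            )

        assert merged_set(out1) == merged_set(out4)

    def test_s2f_f2s_fixed_point(self, tmp_path):
        header, records = fixtures.generate_records(3, mean_length=80, seed=14)
        f5 = fixtures.generate_fast5_fixture(header, records, tmp_path / "x.fast5")
        (b1,) = tools.f2s([f5], tmp_path / "pass1")
        back = tools.s2f(b1, tmp_path / "back.fast5")
        (b2,) = tools.f2s([back], tmp_path / "pass2")
        r1 = sorted(binary_io.read_blow5(b1)[2], key=lambda r: r.read_id)
        r2 = sorted(binary_io.read_blow5(b2)[2], key=lambda r: r.read_id)
        assert r1 == r2

    def test_single_read_layout_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "single.fast5"
        with h5py.File(path, "w") as f:
            f.create_dataset("Raw/Signal", data=np.zeros(4, dtype="<i2"))
        with pytest.raises(UnsupportedFormatError, match="single-read"):
            tools.f2s([path], tmp_path / "out")


class TestCli:
    def test_view_stats_index_parity_with_api(self, small_slow5, tmp_path):
        """CLI commands produce the same artefacts as the library calls."""
        runner = CliRunner()
        out = tmp_path / "cli.blow5"
        result = runner.invoke(
            cli_main, ["view", str(small_slow5), str(out), "--vbz", "--json"]
        )
        assert result.exit_code == 0, result.output
        api_out = tmp_path / "api.blow5"
        tools.view(small_slow5, api_out, config=CompressionConfig.vbz())
        assert list(binary_io.read_blow5(out)[2]) == list(
            binary_io.read_blow5(api_out)[2]
        )

        result = runner.invoke(cli_main, ["stats", str(out), "--json"])
        assert result.exit_code == 0
        assert json.loads(result.stdout)["record_count"] == 50

        result = runner.invoke(cli_main, ["index", str(out), "--json"])
        assert result.exit_code == 0
        assert json.loads(result.stdout)["entries"] == 50

    def test_data_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.slow5"
        bad.write_text("not a slow5 file\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["stats", str(bad)])
        assert result.exit_code == 1

    def test_usage_error_exit_code(self, small_slow5, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["split", str(small_slow5), "-d", str(tmp_path / "o")]
        )
        assert result.exit_code == 2
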