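"""File-level operations: merge, split, stats, and FAST5 conversion.

Everything here is a plain library function; the ``s5`` command-line tool in
:mod:`slow5kit.cli` is a thin wrapper and produces identical results.

FAST5 note: a multi-read FAST5 is an HDF5 container with one group per read
(``read_<id>``) holding the raw signal dataset at ``Raw/Signal``, calibration
attributes under ``channel_id`` and run metadata under ``tracking_id``.  The
exact attribute paths have drifted across instrument software versions;
``FAST5_CALIBRATION_ATTRS`` and ``FAST5_TRACKING_GROUP`` below are the mapping
this converter targets and can be extended by users.  Conversion requires
``h5py``; without it, :class:`UnsupportedEnvironmentError` is raised.
"""

from __future__ import annotations

import hashlib
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import ascii_io, binary_io
from .model import (
    CompressionConfig,
    DuplicateReadIdError,
    FormatError,
    SchemaError,
    Slow5Header,
    Slow5Record,
    UnsupportedEnvironmentError,
    UnsupportedFormatError,
)

try:  # conversion-only optional dependency
    import h5py
except ImportError:  # pragma: no cover - h5py is normally present
    h5py = None

#: group holding per-read calibration attributes inside a FAST5 read group.
FAST5_CHANNEL_GROUP = "channel_id"
#: calibration attribute names, FAST5 -> SLOW5 column.
FAST5_CALIBRATION_ATTRS = {
    "digitisation": "digitisation",
    "offset": "offset",
    "range": "range",
    "sampling_rate": "sampling_rate",
}
#: group holding run metadata that becomes SLOW5 header attributes.
FAST5_TRACKING_GROUP = "tracking_id"
#: dataset path of the raw signal inside a read group.
FAST5_SIGNAL_PATH = "Raw/Signal"


def _write_output(
    path: str | Path,
    header: Slow5Header,
    records: Iterable[Slow5Record],
    config: CompressionConfig | None,
) -> None:
    if str(path).endswith(binary_io.BLOW5_EXTENSION):
        binary_io.write_blow5(header, records, config or CompressionConfig(), path)
    else:
        ascii_io.write_slow5(path, header, records)


# --------------------------------------------------------------------------
# merge
# --------------------------------------------------------------------------


def merge(
    inputs: Sequence[str | Path],
    output: str | Path,
    config: CompressionConfig | None = None,
) -> Slow5Header:
    """Merge SLOW5/BLOW5 files into one, collapsing identical read groups.

    Groups whose attribute maps are identical become a single output group;
    otherwise groups are numbered by first occurrence in input order.  Each
    record's ``read_group`` is remapped accordingly; record content is
    otherwise unchanged.  Duplicate read_ids across inputs and conflicting
    format major versions are errors.
    """
    if not inputs:
        raise ValueError("merge requires at least one input")
    opened = [binary_io.open_any(p) for p in inputs]
    headers = [h for h, _, _ in opened]

    major = headers[0].version_tuple[0]
    version = headers[0].slow5_version
    for h in headers[1:]:
        if h.version_tuple[0] != major:
            raise SchemaError(
                f"conflicting slow5_version majors: {version} vs {h.slow5_version}"
            )
        if h.version_tuple > headers[0].version_tuple:
            version = h.slow5_version

    # group key = frozen attribute map; first occurrence fixes the new index
    group_keys: list[tuple[tuple[str, str], ...]] = []
    key_to_new: dict[tuple[tuple[str, str], ...], int] = {}
    remaps: list[dict[int, int]] = []
    for h in headers:
        remap: dict[int, int] = {}
        for g in range(h.num_read_groups):
            key = tuple(sorted(h.group_attributes(g).items()))
            if key not in key_to_new:
                key_to_new[key] = len(group_keys)
                group_keys.append(key)
            remap[g] = key_to_new[key]
        remaps.append(remap)

    attr_names: list[str] = []
    for key in group_keys:
        for name, _ in key:
            if name not in attr_names:
                attr_names.append(name)
    attributes = {
        name: [dict(key).get(name, "") for key in group_keys] for name in attr_names
    }
    merged = Slow5Header(
        slow5_version=version,
        num_read_groups=len(group_keys),
        attributes=attributes,
        aux_schema=headers[0].aux_schema,
    )
    for h in headers[1:]:
        if h.aux_schema != merged.aux_schema:
            raise SchemaError("cannot merge files with different auxiliary schemas")

    def _records() -> Iterator[Slow5Record]:
        seen: set[str] = set()
        for (h, _, records), remap in zip(opened, remaps):
            for record in records:
                if record.read_id in seen:
                    raise DuplicateReadIdError(
                        f"duplicate read_id {record.read_id!r} across merge inputs"
                    )
                seen.add(record.read_id)
                yield record.copy(read_group=remap[record.read_group])

    _write_output(output, merged, _records(), config)
    return merged


# --------------------------------------------------------------------------
# split
# --------------------------------------------------------------------------


def split_by_group(
    input_path: str | Path,
    out_dir: str | Path,
    config: CompressionConfig | None = None,
) -> list[Path]:
    """One output file per read group, each renumbered to a single group 0."""
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header, _, records = binary_io.open_any(input_path)
    suffix = binary_io.BLOW5_EXTENSION if binary_io.detect_format(input_path) == "blow5" else ascii_io.SLOW5_EXTENSION
    stem = input_path.name
    for ext in (ascii_io.SLOW5_EXTENSION, binary_io.BLOW5_EXTENSION):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    by_group: list[list[Slow5Record]] = [[] for _ in range(header.num_read_groups)]
    for record in records:
        by_group[record.read_group].append(record)
    paths: list[Path] = []
    for g in range(header.num_read_groups):
        sub_header = Slow5Header(
            slow5_version=header.slow5_version,
            num_read_groups=1,
            attributes={name: [values[g]] for name, values in header.attributes.items()},
            aux_schema=header.aux_schema,
        )
        out = out_dir / f"{stem}_group{g}{suffix}"
        _write_output(
            out, sub_header, (r.copy(read_group=0) for r in by_group[g]), config
        )
        paths.append(out)
    return paths


def split_by_reads(
    input_path: str | Path,
    out_dir: str | Path,
    n: int,
    config: CompressionConfig | None = None,
) -> list[Path]:
    """Chunk a file into pieces of ``n`` records (last may be smaller)."""
    if n < 1:
        raise ValueError("chunk size must be >= 1")
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header, _, records = binary_io.open_any(input_path)
    suffix = binary_io.BLOW5_EXTENSION if binary_io.detect_format(input_path) == "blow5" else ascii_io.SLOW5_EXTENSION
    stem = input_path.name
    for ext in (ascii_io.SLOW5_EXTENSION, binary_io.BLOW5_EXTENSION):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    paths: list[Path] = []
    chunk: list[Slow5Record] = []
    part = 0

    def _flush() -> None:
        nonlocal part
        out = out_dir / f"{stem}_part{part}{suffix}"
        _write_output(out, header, chunk, config)
        paths.append(out)
        part += 1

    for record in records:
        chunk.append(record)
        if len(chunk) == n:
            _flush()
            chunk = []
    if chunk:
        _flush()
    return paths


# --------------------------------------------------------------------------
# stats
# --------------------------------------------------------------------------


def stats(input_path: str | Path) -> dict[str, object]:
    """Exact counts for one file: records, groups, signal samples, bytes."""
    input_path = Path(input_path)
    header, config, records = binary_io.open_any(input_path)
    n = 0
    samples = 0
    for record in records:
        n += 1
        samples += int(record.len_raw_signal)
    size = input_path.stat().st_size
    return {
        "path": str(input_path),
        "format": binary_io.detect_format(input_path),
        "record_compression": config.record_method.value,
        "signal_compression": config.signal_method.value,
        "record_count": n,
        "num_read_groups": header.num_read_groups,
        "total_signal_samples": samples,
        "file_bytes": size,
        "bytes_per_sample": (size / samples) if samples else None,
    }


def signal_checksum(records: Iterable[Slow5Record]) -> str:
    """Order-independent digest of all signal content (read_id + samples)."""
    digests = sorted(
        hashlib.blake2b(
            r.read_id.encode() + np.asarray(r.raw_signal, "<i2").tobytes(),
            digest_size=16,
        ).digest()
        for r in records
    )
    return hashlib.blake2b(b"".join(digests), digest_size=16).hexdigest()


# --------------------------------------------------------------------------
# FAST5 conversion
# --------------------------------------------------------------------------


def _require_h5py() -> None:
    if h5py is None:
        raise UnsupportedEnvironmentError(
            "FAST5 conversion requires the optional h5py dependency"
        )


def _read_fast5(path: str | Path) -> tuple[Slow5Header, list[Slow5Record]]:
    """Load one multi-read FAST5 file into a header + records."""
    _require_h5py()
    with h5py.File(path, "r") as f:
        keys = list(f.keys())
        if "Raw" in keys or not any(k.startswith("read_") for k in keys):
            raise UnsupportedFormatError(
                f"{path}: single-read FAST5 (or unrecognised layout) is not supported; "
                "convert to multi-read FAST5 first"
            )
        # read groups keyed by tracking_id attribute map, first occurrence order
        group_keys: list[tuple[tuple[str, str], ...]] = []
        key_to_group: dict[tuple[tuple[str, str], ...], int] = {}
        records: list[Slow5Record] = []
        for key in keys:
            if not key.startswith("read_"):
                continue
            grp = f[key]
            read_id = key[len("read_") :]
            tracking = {}
            if FAST5_TRACKING_GROUP in grp:
                for name, value in grp[FAST5_TRACKING_GROUP].attrs.items():
                    tracking[str(name)] = (
                        value.decode() if isinstance(value, bytes) else str(value)
                    )
            tkey = tuple(sorted(tracking.items()))
            if tkey not in key_to_group:
                key_to_group[tkey] = len(group_keys)
                group_keys.append(tkey)
            channel = grp[FAST5_CHANNEL_GROUP].attrs if FAST5_CHANNEL_GROUP in grp else {}
            signal = np.asarray(grp[FAST5_SIGNAL_PATH][()], dtype=np.int16)
            records.append(
                Slow5Record(
                    read_id=read_id,
                    read_group=key_to_group[tkey],
                    digitisation=float(channel.get("digitisation", 8192.0)),
                    offset=float(channel.get("offset", 0.0)),
                    range=float(channel.get("range", 1.0)),
                    sampling_rate=float(channel.get("sampling_rate", 4000.0)),
                    len_raw_signal=int(signal.size),
                    raw_signal=signal,
                )
            )
    attr_names: list[str] = []
    for tkey in group_keys:
        for name, _ in tkey:
            if name not in attr_names:
                attr_names.append(name)
    header = Slow5Header(
        num_read_groups=max(len(group_keys), 1),
        attributes={
            name: [dict(k).get(name, "") for k in group_keys] for name in attr_names
        },
    )
    return header, records


def f2s(
    inputs: Sequence[str | Path],
    out_dir: str | Path,
    config: CompressionConfig | None = None,
    workers: int = 1,
) -> list[Path]:
    """Convert multi-read FAST5 files to BLOW5, one output per input.

    Work is partitioned at file granularity across ``workers`` independent
    workers; the result is identical for any worker count.
    """
    _require_h5py()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or CompressionConfig.vbz()
    inputs = [Path(p) for p in inputs]

    def _convert_one(path: Path) -> Path:
        header, records = _read_fast5(path)
        out = out_dir / (path.stem + binary_io.BLOW5_EXTENSION)
        binary_io.write_blow5(header, records, config, out)
        return out

    if workers <= 1 or len(inputs) <= 1:
        return [_convert_one(p) for p in inputs]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_convert_one, inputs))


def s2f(input_path: str | Path, output_path: str | Path) -> Path:
    """Convert a SLOW5/BLOW5 file back to a multi-read FAST5 container."""
    _require_h5py()
    header, _, records = binary_io.open_any(input_path)
    output_path = Path(output_path)
    with h5py.File(output_path, "w") as f:
        for record in records:
            grp = f.create_group(f"read_{record.read_id}")
            grp.create_dataset(FAST5_SIGNAL_PATH, data=np.asarray(record.raw_signal, "<i2"))
            ch = grp.create_group(FAST5_CHANNEL_GROUP)
            ch.attrs["digitisation"] = float(record.digitisation)
            ch.attrs["offset"] = float(record.offset)
            ch.attrs["range"] = float(record.range)
            ch.attrs["sampling_rate"] = float(record.sampling_rate)
            tr = grp.create_group(FAST5_TRACKING_GROUP)
            for name, value in header.group_attributes(record.read_group).items():
                tr.attrs[name] = value
    return output_path


def view(
    input_path: str | Path,
    output_path: str | Path,
    encoding: str | None = None,
    config: CompressionConfig | None = None,
) -> binary_io.WriteSummary:
    """Convert between ASCII and binary encodings (the ``s5 view`` operation)."""
    if encoding is None:
        encoding = "blow5" if str(output_path).endswith(binary_io.BLOW5_EXTENSION) else "ascii"
    return binary_io.convert(input_path, output_path, encoding, config)
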