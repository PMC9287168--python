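"""Deterministic synthetic data: random-walk reads and miniature FAST5 files.

Real nanopore current is locally smooth — consecutive ADC samples differ by a
few quantisation levels — which is exactly the property the delta + zig-zag +
StreamVByte signal codec exploits.  The generator therefore emits integer
random walks: ``s[i] = s[i-1] + round(N(0, sigma))`` clipped to int16, with
``sigma = 5`` ADC units and a start level around ``N(500, 30)``.  That is
enough to exercise the compression-ordering behaviour (vbz beating plain
zlib); it is *not* a pore-model simulation and carries no sequence content.

Read lengths are drawn from ``N(mean_length, mean_length/4)``, truncated at 1
sample.  Calibration constants are drawn once per read group.  Everything is
a pure function of the seed and parameters.

``table1_example`` returns the worked single-read-group example file used
throughout the documentation: three reads whose printed signal prefixes are
``498,492`` / ``491,491`` / ``400,400``; signals are padded to the stated
lengths by repeating the last printed value (the padding rule is recorded
here so length-dependent checks are exact while value checks use only the
printed prefixes, exposed in ``TABLE1_SIGNAL_PREFIXES``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Slow5Header, Slow5Record, UnsupportedEnvironmentError

#: default random-walk step standard deviation (ADC units).
DEFAULT_SIGMA = 5.0
#: default mean read length in samples.
DEFAULT_MEAN_LENGTH = 2000
#: read-length standard deviation as a fraction of the mean.
LENGTH_SD_FRACTION = 0.25


def generate_records(
    n: int,
    num_read_groups: int = 1,
    mean_length: int = DEFAULT_MEAN_LENGTH,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    aux: bool = False,
) -> tuple[Slow5Header, list[Slow5Record]]:
    """Generate a header and ``n`` random-walk reads, reproducibly.

    Reads are assigned to ``num_read_groups`` groups round-robin; calibration
    fields are drawn once per group.  With ``aux=True`` the header declares a
    small auxiliary schema (channel number, median level, start sample) and
    every record carries values for it.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if num_read_groups < 1:
        raise ValueError("num_read_groups must be >= 1")
    if mean_length < 1 or sigma <= 0:
        raise ValueError("mean_length must be >= 1 and sigma positive")
    rng = np.random.default_rng(seed)

    attributes = {
        "asic_id": [f"{rng.integers(0, 2**48):012X}" for _ in range(num_read_groups)],
        "exp_start_time": [
            f"2020-01-0{g + 1}T00:00:00Z" for g in range(num_read_groups)
        ],
        "flow_cell_id": [f"FAH{rng.integers(0, 10**5):05d}" for g in range(num_read_groups)],
        "run_id": [f"{rng.integers(0, 2**32):08x}" for _ in range(num_read_groups)],
    }
    calibration = [
        {
            "digitisation": 8192.0,
            "offset": float(rng.integers(-5, 21)),
            "range": float(np.round(rng.uniform(1100.0, 1500.0), 1)),
            "sampling_rate": 4000.0,
        }
        for _ in range(num_read_groups)
    ]
    aux_schema = (
        (("channel_number", "char*"), ("median_before", "double"), ("start_time", "uint64_t"))
        if aux
        else ()
    )
    header = Slow5Header(
        num_read_groups=num_read_groups, attributes=attributes, aux_schema=aux_schema
    )

    records: list[Slow5Record] = []
    for i in range(n):
        group = i % num_read_groups
        length = max(1, int(round(rng.normal(mean_length, LENGTH_SD_FRACTION * mean_length))))
        start = rng.normal(500.0, 30.0)
        steps = np.round(rng.normal(0.0, sigma, size=length)).astype(np.int64)
        steps[0] = int(round(start))
        signal = np.clip(np.cumsum(steps), -32768, 32767).astype(np.int16)
        cal = calibration[group]
        aux_values = (
            {
                "channel_number": str(int(rng.integers(1, 513))),
                "median_before": float(np.round(rng.uniform(150.0, 250.0), 3)),
                "start_time": int(rng.integers(0, 10**9)),
            }
            if aux
            else {}
        )
        records.append(
            Slow5Record(
                read_id=f"read-{seed:x}-{i:06d}",
                read_group=group,
                digitisation=cal["digitisation"],
                offset=cal["offset"],
                range=cal["range"],
                sampling_rate=cal["sampling_rate"],
                len_raw_signal=int(signal.size),
                raw_signal=signal,
                aux_values=aux_values,
            )
        )
    return header, records


# --------------------------------------------------------------------------
# FAST5 fixture
# --------------------------------------------------------------------------


def generate_fast5_fixture(
    header: Slow5Header, records: Sequence[Slow5Record], path: str | Path
) -> Path:
    """Write records into a miniature multi-read FAST5 (HDF5) container.

    Uses the same layout the converter targets: one ``read_<id>`` group per
    read with a ``Raw/Signal`` dataset, ``channel_id`` calibration attributes
    and ``tracking_id`` run metadata.
    """
    try:
        import h5py
    except ImportError as e:  # pragma: no cover
        raise UnsupportedEnvironmentError("FAST5 fixtures require h5py") from e
    path = Path(path)
    with h5py.File(path, "w") as f:
        for record in records:
            grp = f.create_group(f"read_{record.read_id}")
            grp.create_dataset("Raw/Signal", data=np.asarray(record.raw_signal, "<i2"))
            ch = grp.create_group("channel_id")
            ch.attrs["digitisation"] = float(record.digitisation)
            ch.attrs["offset"] = float(record.offset)
            ch.attrs["range"] = float(record.range)
            ch.attrs["sampling_rate"] = float(record.sampling_rate)
            tr = grp.create_group("tracking_id")
            for name, value in header.group_attributes(record.read_group).items():
                tr.attrs[name] = value
    return path


# --------------------------------------------------------------------------
# The worked example file
# --------------------------------------------------------------------------

#: printed signal prefixes of the worked example (values are truncated in
#: print; the remainder of each signal is padding, see ``table1_example``).
TABLE1_SIGNAL_PREFIXES: dict[str, tuple[int, ...]] = {
    "read0": (498, 492),
    "read1": (491, 491),
    "readN": (400, 400),
}

_TABLE1_ROWS = (
    # read_id, offset, len_raw_signal
    ("read0", 6.0, 123456),
    ("read1", 5.0, 2000),
    ("readN", 3.0, 3000),
)


def table1_example() -> tuple[Slow5Header, list[Slow5Record]]:
    """The single-read-group worked example: header and three reads.

    Signal prefixes are exact; the rest of each signal repeats the last
    printed value up to the stated length.
    """
    header = Slow5Header(
        slow5_version="1.0.0",
        num_read_groups=1,
        attributes={
            "asic_id": ["0004A30B00232BEC"],
            "exp_start_time": ["2020-01-01T00:00:00Z"],
            "flow_cell_id": ["FAH00000"],
            "run_id": ["855cdb"],
        },
    )
    records = []
    for read_id, offset, length in _TABLE1_ROWS:
        prefix = TABLE1_SIGNAL_PREFIXES[read_id]
        signal = np.full(length, prefix[-1], dtype=np.int16)
        signal[: len(prefix)] = prefix
        records.append(
            Slow5Record(
                read_id=read_id,
                read_group=0,
                digitisation=8192.0,
                offset=offset,
                range=1467.6,
                sampling_rate=4000.0,
                len_raw_signal=length,
                raw_signal=signal,
            )
        )
    return header, records
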