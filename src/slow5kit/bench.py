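"""Measurement formulas and a parallel random-access throughput harness.

Two small formulas are the comparable quantities:

* normalised CPU utilisation, ``cpu_time / (wall_time * n_threads) * 100`` —
  100% means every requested thread was busy for the whole wall time;
* core-hours, ``n_threads * wall_hours`` — the cost metric that stays
  constant under ideal parallel scaling (halving wall time by doubling
  threads leaves it unchanged).

The harness times indexed random access with a configurable worker count.
Timing numbers describe the current machine and are reported, never asserted;
correctness assertions use the content checksum, which is invariant to worker
count and scheduling.  The harness does not drop the OS page cache (that
needs root and is inherently platform-specific); pass ``pre_run_hook`` to run
your own cache-clearing command before each repetition if you need cold-cache
numbers.
"""

from __future__ import annotations

import hashlib
import time
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .index import RandomAccessReader
from .model import BenchReport, ReadNotFoundError, Slow5Record


def cpu_utilisation(cpu_seconds: float, wall_seconds: float, n_threads: int) -> float:
    """CPU utilisation percentage, normalised by thread count."""
    if wall_seconds <= 0:
        raise ValueError(f"wall time must be positive, got {wall_seconds}")
    if n_threads < 1:
        raise ValueError(f"thread count must be >= 1, got {n_threads}")
    return cpu_seconds / (wall_seconds * n_threads) * 100.0


def core_hours(n_threads: float, wall_hours: float) -> float:
    """Thread count x wall-clock hours."""
    if n_threads < 0 or wall_hours < 0:
        raise ValueError("core_hours arguments must be non-negative")
    return n_threads * wall_hours


def _record_digest(record: Slow5Record) -> bytes:
    return hashlib.blake2b(
        record.read_id.encode() + np.asarray(record.raw_signal, "<i2").tobytes(),
        digest_size=16,
    ).digest()


def access_benchmark(
    data_path: str | Path,
    read_ids: Sequence[str] | None = None,
    sample_size: int | None = None,
    n_workers: int = 1,
    repetitions: int = 1,
    seed: int = 0,
    pre_run_hook: Callable[[], None] | None = None,
) -> BenchReport:
    """Time indexed random access of a read sample with ``n_workers`` threads.

    The sample is drawn (without replacement) from the index with an explicit
    seed unless ``read_ids`` is given, partitioned round-robin across workers,
    and fetched through one shared reader (``os.pread``, no locks).  Reported
    metrics cover the last repetition; per-repetition wall times and their
    mean are included.  Missing ids are collected into ``not_found`` rather
    than raised.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    with RandomAccessReader(data_path) as reader:
        if read_ids is None:
            universe = sorted(reader.index)
            rng = np.random.default_rng(seed)
            if sample_size is None or sample_size >= len(universe):
                sample = universe
            else:
                sample = [universe[i] for i in rng.choice(len(universe), size=sample_size, replace=False)]
        else:
            sample = list(read_ids)
        if not sample:
            raise ValueError("benchmark sample is empty")

        partitions = [sample[w::n_workers] for w in range(n_workers)]

        def _fetch(part: Sequence[str]) -> tuple[list[bytes], list[str]]:
            digests: list[bytes] = []
            missing: list[str] = []
            for rid in part:
                try:
                    digests.append(_record_digest(reader.get(rid)))
                except ReadNotFoundError:
                    missing.append(rid)
            return digests, missing

        rep_wall: list[float] = []
        digests: list[bytes] = []
        missing: list[str] = []
        wall = cpu = 0.0
        for _ in range(repetitions):
            if pre_run_hook is not None:
                pre_run_hook()
            t0, c0 = time.perf_counter(), time.process_time()
            if n_workers == 1:
                results = [_fetch(partitions[0])]
            else:
                with ThreadPoolExecutor(max_workers=n_workers) as pool:
                    results = list(pool.map(_fetch, partitions))
            wall = max(time.perf_counter() - t0, 1e-9)
            cpu = time.process_time() - c0
            rep_wall.append(wall)
            digests = [d for ds, _ in results for d in ds]
            missing = [m for _, ms in results for m in ms]

    checksum = hashlib.blake2b(b"".join(sorted(digests)), digest_size=16).hexdigest()
    accessed = len(digests)
    utilisation = cpu_utilisation(cpu, wall, n_workers)
    return BenchReport(
        n_threads=n_workers,
        wall_seconds=wall,
        cpu_seconds=cpu,
        reads_accessed=accessed,
        reads_per_second=accessed / wall,
        cpu_utilisation_pct=utilisation,
        core_hours=core_hours(n_workers, wall / 3600.0),
        record_checksum=checksum,
        seed=seed,
        not_found=missing,
        rep_wall_seconds=rep_wall,
        mean_wall_seconds=float(np.mean(rep_wall)),
    )
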