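import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from slow5kit import fixtures  # noqa: E402


@pytest.fixture(scope="session")
def table1():
    """The worked single-read-group example: (header, [read0, read1, readN])."""
    return fixtures.table1_example()


@pytest.fixture(scope="session")
def small_dataset():
    """50 short random-walk reads across 2 read groups, with aux fields."""
    return fixtures.generate_records(
        50, num_read_groups=2, mean_length=300, seed=11, aux=True
    )


@pytest.fixture()
def small_slow5(small_dataset, tmp_path):
    from slow5kit import ascii_io

    header, records = small_dataset
    path = tmp_path / "small.slow5"
    ascii_io.write_slow5(path, header, records)
    return path


@pytest.fixture()
def small_blow5(small_dataset, tmp_path):
    from slow5kit import binary_io
    from slow5kit.model import CompressionConfig

    header, records = small_dataset
    path = tmp_path / "small.blow5"
    binary_io.write_blow5(header, records, CompressionConfig.vbz(), path)
    return path
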