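"""Reading and writing SLOW5 ASCII files.

Dialect: tab-separated columns, newline-terminated rows.  The header block
comes first: ``#slow5_version`` and ``#num_read_groups`` structural rows,
``@``-prefixed attribute rows (one tab-separated value per read group), a
``#``-prefixed row of column type tags and a ``#``-prefixed row of column
names.  Data records follow, one read per line, with the raw signal as a
comma-separated list of 16-bit integers.

Doubles are written with the shortest representation that round-trips
(integral values without a decimal point, so ``8192.0`` renders as ``8192``
and ``1467.6`` stays ``1467.6``).  A missing auxiliary value renders as ``.``.
Files are UTF-8 with ``\\n`` line terminators; CRLF is tolerated on read.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import IO, Any, Iterable, Iterator

import numpy as np

from .model import (
    AUX_TYPE_TAGS,
    MISSING,
    NUMERIC_TAG_DTYPES,
    PRIMARY_COLUMNS,
    PRIMARY_TYPE_TAGS,
    FormatError,
    SchemaError,
    Slow5Header,
    Slow5Record,
    ValidationError,
    validate_record,
)

SLOW5_EXTENSION = ".slow5"
MISSING_TOKEN = "."


def format_double(x: float) -> str:
    """Shortest round-trip rendering; integral doubles drop the decimal point."""
    x = float(x)
    if x.is_integer() and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


# --------------------------------------------------------------------------
# Auxiliary field rendering/parsing
# --------------------------------------------------------------------------


def _render_aux(value: Any, tag: str) -> str:
    if value is MISSING:
        return MISSING_TOKEN
    if tag == "char":
        s = str(value)
        if len(s) != 1:
            raise ValidationError(f"char auxiliary value {s!r} is not a single character")
        return s
    if tag == "char*":
        s = str(value)
        if "\t" in s or "\n" in s:
            raise ValidationError(f"string auxiliary value {s!r} contains a delimiter")
        return s
    if tag.endswith("*"):  # numeric array
        base = tag[:-1]
        arr = np.asarray(value, dtype=NUMERIC_TAG_DTYPES[base])
        if base in ("float", "double"):
            return ",".join(format_double(v) for v in arr.tolist())
        return ",".join(str(v) for v in arr.tolist())
    if tag in ("float", "double"):
        return format_double(float(value))
    return str(int(value))


def _parse_aux(cell: str, tag: str) -> Any:
    if cell == MISSING_TOKEN:
        return MISSING
    if tag == "char":
        if len(cell) != 1:
            raise FormatError(f"char auxiliary cell {cell!r} is not a single character")
        return cell
    if tag == "char*":
        return cell
    if tag.endswith("*"):
        base = tag[:-1]
        if cell == "":
            return np.array([], dtype=NUMERIC_TAG_DTYPES[base])
        try:
            return np.array(cell.split(","), dtype=NUMERIC_TAG_DTYPES[base])
        except (ValueError, OverflowError) as e:
            raise FormatError(f"bad {tag} auxiliary cell {cell!r}: {e}") from e
    try:
        if tag in ("float", "double"):
            return float(cell)
        return int(cell)
    except ValueError as e:
        raise FormatError(f"bad {tag} auxiliary cell {cell!r}: {e}") from e


# --------------------------------------------------------------------------
# Header
# --------------------------------------------------------------------------


def _strip_eol(line: str) -> str:
    return line.rstrip("\n").rstrip("\r")


def parse_header(source: IO[str] | Iterator[str]) -> Slow5Header:
    """Consume the header block from a line source.

    Reads ``#`` and ``@`` rows up to and including the column-name row and
    leaves the source positioned at the first data row.  ``source`` may be a
    text file object or any iterator of lines.
    """
    readline = source.readline if hasattr(source, "readline") else lambda: next(source, "")
    version: str | None = None
    num_groups: int | None = None
    attributes: dict[str, list[str]] = {}
    type_row: list[str] | None = None

    while True:
        line = readline()
        if not line:
            raise FormatError("unexpected end of file inside SLOW5 header")
        line = _strip_eol(line)
        if line.startswith("@"):
            cells = line.split("\t")
            name = cells[0][1:]
            if not name:
                raise SchemaError("attribute row with empty name")
            values = cells[1:]
            if num_groups is None:
                raise FormatError("attribute row before #num_read_groups")
            if len(values) != num_groups:
                raise SchemaError(
                    f"attribute {name!r} has {len(values)} values for {num_groups} read group(s)"
                )
            attributes[name] = values
        elif line.startswith("#"):
            cells = line.split("\t")
            key = cells[0][1:]
            if key == "slow5_version":
                if len(cells) != 2:
                    raise FormatError("malformed #slow5_version row")
                version = cells[1]
            elif key == "num_read_groups":
                if len(cells) != 2:
                    raise FormatError("malformed #num_read_groups row")
                try:
                    num_groups = int(cells[1])
                except ValueError as e:
                    raise FormatError(f"bad num_read_groups {cells[1]!r}") from e
            elif key in AUX_TYPE_TAGS or key in PRIMARY_TYPE_TAGS:
                type_row = [key] + cells[1:]
                break
            else:
                raise FormatError(f"unrecognised header row {cells[0]!r}")
        else:
            raise FormatError(
                "data row encountered before the column type and name rows"
            )

    if version is None:
        raise FormatError("missing #slow5_version header row")
    if num_groups is None:
        raise FormatError("missing #num_read_groups header row")

    name_line = readline()
    if not name_line:
        raise FormatError("missing column name row")
    name_cells = _strip_eol(name_line).split("\t")
    if not name_cells[0].startswith("#"):
        raise FormatError("column name row must start with '#'")
    name_cells[0] = name_cells[0][1:]
    if len(name_cells) != len(type_row):
        raise SchemaError(
            f"type row has {len(type_row)} columns but name row has {len(name_cells)}"
        )
    if tuple(name_cells[:8]) != PRIMARY_COLUMNS or tuple(type_row[:8]) != PRIMARY_TYPE_TAGS:
        raise SchemaError("primary column schema does not match the SLOW5 specification")
    aux_schema = tuple(zip(name_cells[8:], type_row[8:]))

    header = Slow5Header(
        slow5_version=version,
        num_read_groups=num_groups,
        attributes=attributes,
        aux_schema=aux_schema,
    )
    header.validate()
    return header


def write_header(header: Slow5Header) -> str:
    """Render the header block, ending with a trailing newline."""
    header.validate()
    lines = [
        f"#slow5_version\t{header.slow5_version}",
        f"#num_read_groups\t{header.num_read_groups}",
    ]
    for name, values in header.attributes.items():
        lines.append("@" + name + "".join("\t" + v for v in values))
    type_tags = list(PRIMARY_TYPE_TAGS) + [tag for _, tag in header.aux_schema]
    names = list(PRIMARY_COLUMNS) + [name for name, _ in header.aux_schema]
    lines.append("#" + "\t".join(type_tags))
    lines.append("#" + "\t".join(names))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------


def parse_record(line: str, header: Slow5Header) -> Slow5Record:
    """Parse one data row (without its trailing newline) into a record."""
    line = _strip_eol(line)
    cells = line.split("\t")
    expected = 8 + len(header.aux_schema)
    if len(cells) != expected:
        raise FormatError(
            f"data row has {len(cells)} columns, expected {expected}"
        )
    try:
        read_group = int(cells[1])
        digitisation = float(cells[2])
        offset = float(cells[3])
        range_ = float(cells[4])
        sampling_rate = float(cells[5])
        len_raw = int(cells[6])
    except ValueError as e:
        raise FormatError(f"bad numeric cell in record {cells[0]!r}: {e}") from e
    sig_cell = cells[7]
    if sig_cell == "":
        signal = np.array([], dtype=np.int16)
    else:
        try:
            signal = np.array(sig_cell.split(","), dtype=np.int64)
        except (ValueError, OverflowError) as e:
            raise FormatError(f"bad raw_signal cell in record {cells[0]!r}: {e}") from e
        if signal.size and (signal.min() < -32768 or signal.max() > 32767):
            raise FormatError(
                f"raw_signal value out of int16 range in record {cells[0]!r}"
            )
        signal = signal.astype(np.int16)
    if len_raw != signal.size:
        raise FormatError(
            f"record {cells[0]!r}: len_raw_signal {len_raw} does not match "
            f"{signal.size} signal values"
        )
    aux_values = {
        name: _parse_aux(cell, tag)
        for (name, tag), cell in zip(header.aux_schema, cells[8:])
    }
    return Slow5Record(
        read_id=cells[0],
        read_group=read_group,
        digitisation=digitisation,
        offset=offset,
        range=range_,
        sampling_rate=sampling_rate,
        len_raw_signal=len_raw,
        raw_signal=signal,
        aux_values=aux_values,
    )


def write_record(record: Slow5Record, header: Slow5Header) -> str:
    """Render one record as a data row (no trailing newline)."""
    violations = validate_record(record, header)
    if violations:
        raise ValidationError(
            f"record {record.read_id!r} is invalid: " + "; ".join(violations)
        )
    sig = np.asarray(record.raw_signal, dtype=np.int16)
    cells = [
        record.read_id,
        str(int(record.read_group)),
        format_double(record.digitisation),
        format_double(record.offset),
        format_double(record.range),
        format_double(record.sampling_rate),
        str(int(record.len_raw_signal)),
        ",".join(map(str, sig.tolist())),
    ]
    for name, tag in header.aux_schema:
        cells.append(_render_aux(record.aux_values.get(name, MISSING), tag))
    return "\t".join(cells)


# --------------------------------------------------------------------------
# Whole files (streaming)
# --------------------------------------------------------------------------


def read_slow5(path: str | Path) -> tuple[Slow5Header, Iterator[Slow5Record]]:
    """Open a SLOW5 ASCII file; return its header and a lazy record iterator.

    Records are parsed one line at a time (constant memory per record); the
    underlying file is closed when the iterator is exhausted or closed.
    """
    fh = open(path, "r", encoding="utf-8", newline="")
    try:
        header = parse_header(fh)
    except Exception:
        fh.close()
        raise

    def _records() -> Iterator[Slow5Record]:
        try:
            for line in fh:
                if line.strip("\r\n") == "":
                    continue
                yield parse_record(line, header)
        finally:
            fh.close()

    return header, _records()


def write_slow5(
    path: str | Path, header: Slow5Header, records: Iterable[Slow5Record]
) -> int:
    """Write a SLOW5 ASCII file one record at a time; return the record count."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(write_header(header))
        for record in records:
            fh.write(write_record(record, header))
            fh.write("\n")
            n += 1
    return n


def dumps(header: Slow5Header, records: Iterable[Slow5Record]) -> str:
    """Render a complete SLOW5 ASCII file as a string."""
    buf = io.StringIO()
    buf.write(write_header(header))
    for record in records:
        buf.write(write_record(record, header))
        buf.write("\n")
    return buf.getvalue()


def loads(text: str) -> tuple[Slow5Header, list[Slow5Record]]:
    """Parse a complete SLOW5 ASCII file from a string."""
    buf = io.StringIO(text)
    header = parse_header(buf)
    records = [parse_record(line, header) for line in buf if line.strip("\r\n")]
    return header, records
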