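"""Spreadsheet-style fixture tables: karyotype strings vs expected classes.

The fixture CSV mirrors the document-centric test style used for curated
karyotype collections: column 1 is the ISCN string, column 2 whether it
should parse at all, and every remaining column is a defined-class name with
true/false expectations.  Running the table checks the parser and the
classifier together.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .band_map import BandMap
from .classification import classify, get_class, UnregisteredNameError
from .parser import ParseError, parse


class FixtureFormatError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureRow:
    iscn: str
    parsable: bool
    expectations: dict[str, bool]


@dataclass(frozen=True)
class RowResult:
    iscn: str
    passed: bool
    failures: tuple[str, ...]


def _parse_bool(cell: str, where: str) -> bool:
    v = cell.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise FixtureFormatError(f"{where}: expected true/false, got {cell!r}")


def read_fixture_table(source) -> list[FixtureRow]:
    """Read a fixture CSV (header: iscn, parsable, then class-name columns)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8", newline="") as fh:
            lines = fh.read().splitlines()
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise FixtureFormatError("empty fixture table") from None
    if len(header) < 3 or header[0] != "iscn" or header[1] != "parsable":
        raise FixtureFormatError("header must be: iscn, parsable, <class names...>")
    class_names = header[2:]
    for name in class_names:
        try:
            get_class(name)  # class-name columns are case-sensitive
        except UnregisteredNameError:
            raise FixtureFormatError(f"unknown class column {name!r}") from None

    rows: list[FixtureRow] = []
    for lineno, cells in enumerate(reader, start=2):
        if not cells or not any(c.strip() for c in cells):
            continue
        if len(cells) != len(header):
            raise FixtureFormatError(f"line {lineno}: expected {len(header)} cells")
        expectations = {}
        for name, cell in zip(class_names, cells[2:]):
            if cell.strip():  # blank cell: no expectation for this class
                expectations[name] = _parse_bool(cell, f"line {lineno}, column {name}")
        parsable = _parse_bool(cells[1], f"line {lineno}, column parsable")
        if parsable and not expectations:
            raise FixtureFormatError(f"line {lineno}: at least one expectation required")
        rows.append(FixtureRow(cells[0].strip(), parsable, expectations))
    return rows


def run_fixtures(rows: Iterable[FixtureRow], band_map: BandMap) -> list[RowResult]:
    """Check each row's parsability and class expectations against the code."""
    results: list[RowResult] = []
    for row in rows:
        failures: list[str] = []
        try:
            k = parse(row.iscn, band_map)
        except ParseError as exc:
            if row.parsable:
                failures.append(f"expected parsable, got: {exc}")
            results.append(RowResult(row.iscn, not failures, tuple(failures)))
            continue
        if not row.parsable:
            failures.append("expected unparsable, but parsed")
        else:
            classes = classify(k)
            for name, expected in row.expectations.items():
                actual = name in classes
                if actual != expected:
                    failures.append(f"{name}: expected {expected}, got {actual}")
        results.append(RowResult(row.iscn, not failures, tuple(failures)))
    return results


def default_fixture_rows() -> list[FixtureRow]:
    """The packaged fixture table."""
    text = resources.files("karyokit.data").joinpath("fixtures.csv").read_text("utf-8")
    import io

    return read_fixture_table(io.StringIO(text))
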