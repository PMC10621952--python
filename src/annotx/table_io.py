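"""Reading interval tables (BED, VCF, custom delimited text) and writing
column-appended output.

The cardinal rule of the writer is that the user's columns pass through
byte-identically: annotation is appended as extra columns, never merged
into or reordered with the original ones.  Comment lines are passed
through untouched and unannotated.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, TextIO, Union

from .coordinate_engine import (
    BED_CONVENTION,
    GFF_CONVENTION,
    CoordinateConvention,
    normalize,
)
from .errors import ConfigurationError, InvalidIntervalError, TableFormatError

log = logging.getLogger("annotx")


@dataclass
class TableSchema:
    """Where to find the interval fields in an input table.

    Column indices are 1-based.  For ``bed`` and ``vcf`` the indices and
    coordinate convention are fixed by the format standard; only
    ``custom`` tables take user-specified columns, separator, convention
    and header policy (``present``/``absent``/``auto``).
    """

    format: str  # bed | vcf | custom
    separator: str = "\t"
    id_col: Optional[int] = None
    ref_col: Optional[int] = None
    start_col: Optional[int] = None
    end_col: Optional[int] = None
    convention: CoordinateConvention = GFF_CONVENTION
    header: str = "auto"

    @classmethod
    def bed(cls) -> "TableSchema":
        return cls(format="bed", ref_col=1, start_col=2, end_col=3, id_col=4,
                   convention=BED_CONVENTION, header="absent")

    @classmethod
    def vcf(cls) -> "TableSchema":
        return cls(format="vcf", ref_col=1, start_col=2, id_col=3,
                   convention=GFF_CONVENTION, header="absent")

    @classmethod
    def custom(
        cls,
        id_col: int,
        ref_col: int,
        start_col: int,
        end_col: int,
        separator: str = "\t",
        base: int = 1,
        header: str = "auto",
    ) -> "TableSchema":
        for name, val in (("id_col", id_col), ("ref_col", ref_col),
                          ("start_col", start_col), ("end_col", end_col)):
            if not isinstance(val, int) or val < 1:
                raise ConfigurationError(f"custom schema requires a positive {name}")
        convention = BED_CONVENTION if base == 0 else GFF_CONVENTION
        return cls(format="custom", separator=separator, id_col=id_col,
                   ref_col=ref_col, start_col=start_col, end_col=end_col,
                   convention=convention, header=header)


@dataclass
class IntervalRecord:
    """One data row of the input table, with its canonical interval.

    ``start``/``end`` are 1-based inclusive (None when the row's interval
    failed validation — such rows are still emitted, unannotated and
    flagged).  ``original_line`` is the verbatim input line without its
    terminator.
    """

    row_number: int
    id: str
    reference: str
    start: Optional[int]
    end: Optional[int]
    original_line: str
    invalid_reason: Optional[str] = None


@dataclass
class PassthroughLine:
    """A comment or header line reproduced verbatim in the output."""

    row_number: int
    text: str
    is_header: bool = False


@dataclass
class MalformedLine:
    """An unparseable data row: skipped with a warning."""

    row_number: int
    text: str
    reason: str


TableItem = Union[IntervalRecord, PassthroughLine, MalformedLine]


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


class TableReader:
    """Streaming reader producing :class:`IntervalRecord` items.

    Counts malformed rows; if they exceed half of all data rows the run
    aborts with :class:`TableFormatError` once iteration finishes.
    """

    def __init__(self, source: Union[str, TextIO], schema: TableSchema):
        self.source = source
        self.schema = schema
        self.n_rows = 0
        self.n_malformed = 0
        self.had_header = False

    def __iter__(self) -> Iterator[TableItem]:
        if isinstance(self.source, str):
            fh = open(self.source)
            close = True
        else:
            fh, close = self.source, False
        try:
            yield from self._parse(fh)
        finally:
            if close:
                fh.close()
        if self.n_rows and self.n_malformed * 2 > self.n_rows:
            raise TableFormatError(
                f"{self.n_malformed} of {self.n_rows} rows malformed; "
                "check the schema (separator, column indices)"
            )

    # -- internals ---------------------------------------------------------

    def _parse(self, fh: TextIO) -> Iterator[TableItem]:
        schema = self.schema
        pending_first_data = schema.format == "custom" and schema.header in ("auto", "present")
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if self._is_comment(line):
                yield PassthroughLine(lineno, line)
                continue
            if not line.strip():
                yield PassthroughLine(lineno, line)
                continue
            if pending_first_data:
                pending_first_data = False
                if schema.header == "present" or self._looks_like_header(line):
                    self.had_header = True
                    yield PassthroughLine(lineno, line, is_header=True)
                    continue
            yield self._parse_row(lineno, line)

    def _is_comment(self, line: str) -> bool:
        if self.schema.format == "vcf":
            return line.startswith("#")
        if self.schema.format == "bed":
            return line.startswith(("#", "track ", "track\t", "browser "))
        return line.startswith("#")

    def _looks_like_header(self, line: str) -> bool:
        fields = line.split(self.schema.separator)
        s = self.schema
        for col in (s.start_col, s.end_col):
            if col > len(fields) or not _is_int(fields[col - 1]):
                return True
        return False

    def _parse_row(self, lineno: int, line: str) -> TableItem:
        s = self.schema
        self.n_rows += 1
        fields = line.split(s.separator)
        needed = [c for c in (s.id_col, s.ref_col, s.start_col, s.end_col) if c]
        if s.format == "bed":
            needed = [s.ref_col, s.start_col, s.end_col]  # name column optional
        if s.format == "vcf":
            needed = [s.ref_col, s.start_col, 4]  # CHROM POS . REF
        if max(needed) > len(fields):
            self.n_malformed += 1
            log.warning("row %d: expected at least %d columns, found %d; skipped",
                        lineno, max(needed), len(fields))
            return MalformedLine(lineno, line, "too few columns")
        try:
            if s.format == "vcf":
                ref = fields[0]
                pos = int(fields[1])
                raw_id = fields[2]
                rid = raw_id if raw_id not in (".", "") else f"{ref}:{pos}"
                start, end = pos, pos + len(fields[3]) - 1
            else:
                ref = fields[s.ref_col - 1]
                start = int(fields[s.start_col - 1])
                end = int(fields[s.end_col - 1])
                if s.format == "bed" and (s.id_col is None or s.id_col > len(fields)):
                    rid = f"{ref}:{fields[s.start_col - 1]}-{fields[s.end_col - 1]}"
                else:
                    rid = fields[s.id_col - 1]
        except ValueError as exc:
            self.n_malformed += 1
            log.warning("row %d: %s; skipped", lineno, exc)
            return MalformedLine(lineno, line, str(exc))
        try:
            cstart, cend = normalize(start, end, s.convention)
        except InvalidIntervalError as exc:
            log.warning("row %d: %s; emitted unannotated", lineno, exc)
            return IntervalRecord(lineno, rid, ref, None, None, line,
                                  invalid_reason=str(exc))
        return IntervalRecord(lineno, rid, ref, cstart, cend, line)


def read_intervals(source: Union[str, TextIO], schema: TableSchema) -> Iterator[TableItem]:
    """Stream a table as :class:`IntervalRecord`/passthrough items."""
    return iter(TableReader(source, schema))


def write_annotated(
    items: Iterable,
    column_names: List[str],
    schema: TableSchema,
    out: Optional[TextIO] = None,
) -> int:
    """Write annotated output: each input line plus appended columns.

    *items* mixes :class:`PassthroughLine` objects and ``(IntervalRecord,
    [values...])`` pairs produced by the annotator.  A single header line
    names the appended columns; when the input had no header, placeholder
    names (``column_1`` ...) stand in for the original columns.  Returns
    the number of data lines written.
    """
    out = out if out is not None else sys.stdout
    sep = schema.separator
    wrote_header = False
    n = 0
    for item in items:
        if isinstance(item, PassthroughLine):
            if item.is_header and not wrote_header:
                out.write(item.text + sep + sep.join(column_names) + "\n")
                wrote_header = True
            else:
                out.write(item.text + "\n")
            continue
        if isinstance(item, MalformedLine):
            continue
        record, rows = item
        if not wrote_header:
            width = len(record.original_line.split(sep))
            placeholders = [f"column_{i + 1}" for i in range(width)]
            out.write(sep.join(placeholders + column_names) + "\n")
            wrote_header = True
        for values in rows:
            out.write(record.original_line + sep + sep.join(values) + "\n")
            n += 1
    return n
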