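"""Reading and writing correlation tables.

The on-disk format is a plain comma-delimited file whose header line must be
exactly::

    variable1,var1_domain,variable2,var2_domain,coef

(cosmetic whitespace around each header field is tolerated, the names and
their order are not). Each data row holds one pairwise correlation: two
variable labels, the domain (category) each belongs to, and a signed
correlation coefficient. This is the interchange format produced by
spreadsheet exports of pairwise correlation analyses — for example a table of
microbial-taxon abundances correlated against each other and against
clinical or environmental metadata.

Dialect notes: standard double-quote CSV quoting, LF or CRLF line endings,
UTF-8 with an optional byte-order mark, blank lines ignored. Extra columns
after ``coef`` are rejected (the header would not match). Coefficients
outside [-1, +1] are rejected unless ``permissive=True``, which downgrades
the violation to a warning for users feeding covariance-like scores.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from dataclasses import dataclass
from typing import IO, Iterator, Sequence, Union

from .errors import BadCoefficient, EmptyTable, HeaderMismatch, MalformedRow

logger = logging.getLogger(__name__)

#: The exact header contract, in column order.
REQUIRED_HEADER: tuple[str, ...] = (
    "variable1",
    "var1_domain",
    "variable2",
    "var2_domain",
    "coef",
)

PathOrStream = Union[str, os.PathLike, IO[str]]


@dataclass(frozen=True)
class CorrelationRecord:
    """One pairwise correlation as read from a source file.

    ``row_index`` is the 0-based position among the data rows of the source
    (provenance; the header is not counted). The physical 1-based file line,
    used in error messages, is tracked separately by the reader because blank
    lines and quoted newlines can shift it.
    """

    variable1: str
    domain1: str
    variable2: str
    domain2: str
    coef: float
    row_index: int

    def endpoints(self) -> frozenset[tuple[str, str]]:
        """Unordered pair identity: {(variable1, domain1), (variable2, domain2)}."""
        return frozenset(
            [(self.variable1, self.domain1), (self.variable2, self.domain2)]
        )


@dataclass(frozen=True)
class CorrelationTable:
    """An ordered collection of records; order equals source-file row order."""

    records: tuple[CorrelationRecord, ...]
    source_name: str = "<synthetic>"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CorrelationRecord]:
        return iter(self.records)


def _is_blank(row: Sequence[str]) -> bool:
    return not row or all(f.strip() == "" for f in row)


def read_correlations(source: PathOrStream, permissive: bool = False) -> CorrelationTable:
    """Parse a correlation CSV into a :class:`CorrelationTable`.

    Parameters
    ----------
    source:
        A path or an open text stream.
    permissive:
        If true, coefficients outside [-1, +1] are kept with a warning
        instead of raising :class:`~corrglobe.errors.BadCoefficient`.

    Raises
    ------
    HeaderMismatch
        The header is not the five required names in order.
    BadCoefficient
        A coefficient fails to parse, is non-finite, or (non-permissive)
        falls outside [-1, +1]; the error carries the 1-based line number.
    MalformedRow
        Wrong field count or an empty variable/domain label.
    EmptyTable
        Header only, no data rows.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8-sig", newline="") as fh:
            return _read(fh, str(source), permissive)
    return _read(source, getattr(source, "name", "<stream>"), permissive)


def _read(fh: IO[str], name: str, permissive: bool) -> CorrelationTable:
    reader = csv.reader(fh)

    header = None
    for row in reader:
        if _is_blank(row):
            continue
        header = row
        break
    if header is None:
        raise HeaderMismatch(())
    # Streams opened without utf-8-sig may leave a BOM on the first field.
    header = [f.strip().lstrip("\ufeff") for f in header]
    if tuple(header) != REQUIRED_HEADER:
        raise HeaderMismatch(tuple(header))

    records: list[CorrelationRecord] = []
    for row in reader:
        if _is_blank(row):
            continue
        line = reader.line_num  # physical line, 1-based, header counted
        if len(row) != 5:
            raise MalformedRow(line, f"expected 5 fields, found {len(row)}")
        v1, d1, v2, d2, raw = (f.strip() for f in row)
        for label, what in ((v1, "variable1"), (d1, "var1_domain"),
                            (v2, "variable2"), (d2, "var2_domain")):
            if not label:
                raise MalformedRow(line, f"empty {what} label")
        try:
            coef = float(raw)
        except ValueError:
            raise BadCoefficient(line, raw, "not a number") from None
        if not math.isfinite(coef):
            raise BadCoefficient(line, raw, "not finite")
        if abs(coef) > 1.0:
            if not permissive:
                raise BadCoefficient(line, raw, "outside [-1, 1]")
            logger.warning(
                "COEF_RANGE line %d: coefficient %s outside [-1, 1] kept "
                "(permissive mode)", line, raw,
            )
        records.append(
            CorrelationRecord(v1, d1, v2, d2, coef, row_index=len(records))
        )

    if not records:
        raise EmptyTable(f"{name}: header only, no data rows")
    return CorrelationTable(tuple(records), source_name=name)


def write_correlations(table: CorrelationTable, sink: PathOrStream) -> None:
    """Write ``table`` in the header-contract CSV format.

    Coefficients are written with ``repr`` so that a write/read round trip
    reproduces every float bit-for-bit. Labels containing commas, quotes or
    other CSV metacharacters are quoted per the standard convention.
    """
    if not table.records:
        raise EmptyTable("refusing to write a table with no records")
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            _write(table, fh)
    else:
        _write(table, sink)


def _write(table: CorrelationTable, fh: IO[str]) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(REQUIRED_HEADER)
    for rec in table.records:
        writer.writerow(
            [rec.variable1, rec.domain1, rec.variable2, rec.domain2, repr(rec.coef)]
        )
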