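"""Row-at-a-time table serialization with a frozen header layout.

This is the core of the package: instead of materialising a whole study or
assay table and writing it in one go, an output sink is opened, each row is
rendered and flushed as it arrives, and no reference to it is kept.  Memory
use is therefore independent of the number of rows, which makes tables too
big to fit in memory writable.  The price of the contract is that the column
layout is derived from the first row and frozen: a later row whose structure
would require different columns is an error, never a silent widening,
because headers cannot be modified once they are written.

The sink can be a filesystem path or any object with a ``write(str)`` method
— an in-memory buffer, an HTTP response body, or a digest/compression
adapter — so the output can be piped into further processing such as
checksumming or compressing.

Column grammar
--------------
Per node: the role's name column (``Source Name``, ``Sample Name``,
``Raw Data File`` ...), then ``Characteristics[c]`` columns, then
``Factor Value[f]`` columns, then ``Comment[c]`` columns, each in the
node's attribute insertion order.  Per process: ``Protocol REF``, then
``Parameter Value[p]`` columns, then ``Date`` and ``Performer`` when
present, then comments.  An ontology-annotated value expands with
``Term Source REF`` and ``Term Accession Number`` columns; a unit appends
``Unit`` (plus the term columns again when the unit itself is annotated).
"""

from __future__ import annotations

import hashlib
import io
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .errors import (
    RowStructureError,
    StreamStateError,
    StructureError,
)
from .model import (
    AttributeKind,
    AttributeValue,
    MetadataNode,
    OntologyAnnotation,
    ProcessStep,
    TableRow,
)

__all__ = [
    "ColumnDescriptor",
    "DigestSink",
    "HeaderSignature",
    "NullSink",
    "TableStream",
    "WriteStats",
    "derive_header",
    "escape_field",
    "open_table",
    "render_header_line",
    "render_row_line",
]

LINE_ENDING = "\n"

# cell parts a column can read from its chain element
_NAME = "name"
_PROTOCOL = "protocol_ref"
_DATE = "date"
_PERFORMER = "performer"
_VALUE = "value"
_TSR = "term_source"
_TAN = "term_accession"
_UNIT = "unit"
_UNIT_TSR = "unit_term_source"
_UNIT_TAN = "unit_term_accession"


@dataclass(frozen=True, slots=True)
class ColumnDescriptor:
    """One output column: its header text plus where in the row chain it reads from.

    ``origin`` is ``(chain_index, part, kind, category)``; ``kind`` and
    ``category`` are empty for structural parts (names, ``Protocol REF``,
    ``Date``, ``Performer``).
    """

    header_text: str
    chain_index: int
    part: str
    kind: str = ""
    category: str = ""


@dataclass(frozen=True)
class HeaderSignature:
    """The ordered column layout derived from the first row; frozen thereafter."""

    columns: tuple[ColumnDescriptor, ...]

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def header_texts(self) -> tuple[str, ...]:
        return tuple(c.header_text for c in self.columns)


def escape_field(value: str) -> str:
    """Quote a field for the tab-separated dialect.

    A field containing a tab, a line break, or a double quote is wrapped in
    double quotes with internal quotes doubled; anything else passes through
    unchanged.  This round-trips through standard delimited-text readers
    configured for tab delimiter and ``"`` quote character.
    """
    if "\t" in value or "\n" in value or "\r" in value or '"' in value:
        return '"' + value.replace('"', '""') + '"'
    return value


def _expand_value(
    columns: list[ColumnDescriptor], idx: int, attr: AttributeValue, header: str
) -> None:
    kind = attr.kind.value
    columns.append(ColumnDescriptor(header, idx, _VALUE, kind, attr.category))
    if isinstance(attr.value, OntologyAnnotation):
        columns.append(ColumnDescriptor("Term Source REF", idx, _TSR, kind, attr.category))
        columns.append(ColumnDescriptor("Term Accession Number", idx, _TAN, kind, attr.category))
    if attr.unit is not None:
        columns.append(ColumnDescriptor("Unit", idx, _UNIT, kind, attr.category))
        if isinstance(attr.unit, OntologyAnnotation):
            columns.append(ColumnDescriptor("Term Source REF", idx, _UNIT_TSR, kind, attr.category))
            columns.append(
                ColumnDescriptor("Term Accession Number", idx, _UNIT_TAN, kind, attr.category)
            )


def _node_columns(columns: list[ColumnDescriptor], idx: int, node: MetadataNode) -> None:
    columns.append(ColumnDescriptor(node.node_role.name_header, idx, _NAME))
    for wanted in (AttributeKind.CHARACTERISTIC, AttributeKind.FACTOR_VALUE):
        for attr in node.attributes:
            if attr.kind is wanted:
                _expand_value(columns, idx, attr, f"{wanted.header_prefix}[{attr.category}]")
    for attr in node.attributes:
        if attr.kind is AttributeKind.COMMENT:
            _expand_value(columns, idx, attr, f"Comment[{attr.category}]")


def _process_columns(columns: list[ColumnDescriptor], idx: int, process: ProcessStep) -> None:
    columns.append(ColumnDescriptor("Protocol REF", idx, _PROTOCOL))
    for attr in process.attributes:
        if attr.kind is AttributeKind.PARAMETER_VALUE:
            _expand_value(columns, idx, attr, f"Parameter Value[{attr.category}]")
    if process.date is not None:
        columns.append(ColumnDescriptor("Date", idx, _DATE))
    if process.performer is not None:
        columns.append(ColumnDescriptor("Performer", idx, _PERFORMER))
    for attr in process.attributes:
        if attr.kind is AttributeKind.COMMENT:
            _expand_value(columns, idx, attr, f"Comment[{attr.category}]")


def derive_header(row: TableRow) -> HeaderSignature:
    """Derive the deterministic column layout of ``row``.

    Equal rows (same structure and attribute order) yield equal signatures.
    """
    if not isinstance(row, TableRow):
        raise StructureError(f"expected a TableRow, got {row!r}")
    columns: list[ColumnDescriptor] = []
    for idx, element in enumerate(row.chain):
        if idx % 2 == 0:
            _node_columns(columns, idx, element)
        else:
            _process_columns(columns, idx, element)
    return HeaderSignature(columns=tuple(columns))


def render_header_line(sig: HeaderSignature) -> str:
    """Render the header texts as one tab-joined, escaped, LF-terminated line."""
    if not sig.columns:
        raise StructureError("cannot render an empty header signature")
    return "\t".join(escape_field(c.header_text) for c in sig.columns) + LINE_ENDING


def _attr_cell(attr: AttributeValue, part: str) -> str:
    value = attr.value
    if part == _VALUE:
        return value.term if isinstance(value, OntologyAnnotation) else value
    if part == _TSR:
        return value.source_name if isinstance(value, OntologyAnnotation) else ""
    if part == _TAN:
        return value.accession if isinstance(value, OntologyAnnotation) else ""
    unit = attr.unit
    if part == _UNIT:
        if unit is None:
            return ""
        return unit.term if isinstance(unit, OntologyAnnotation) else unit
    if part == _UNIT_TSR:
        return unit.source_name if isinstance(unit, OntologyAnnotation) else ""
    if part == _UNIT_TAN:
        return unit.accession if isinstance(unit, OntologyAnnotation) else ""
    raise StructureError(f"unknown cell part {part!r}")


def _find_attr(element, kind: str, category: str) -> AttributeValue:
    for attr in element.attributes:
        if attr.kind.value == kind and attr.category == category:
            return attr
    raise RowStructureError(f"row is missing attribute ({kind}, {category!r})")


def render_row_line(row: TableRow, sig: HeaderSignature) -> str:
    """Render one row against a frozen signature; one escaped cell per column.

    The row's own derived layout must equal ``sig``; otherwise a
    :class:`RowStructureError` names the first differing column.  Absent
    optional cells (empty accessions and the like) are emitted as empty
    fields, never omitted, so every line has exactly ``len(sig)`` fields.
    """
    check_signature_match(row, sig)
    cells: list[str] = []
    for col in sig.columns:
        element = row.chain[col.chain_index]
        if col.part == _NAME:
            cells.append(element.name)
        elif col.part == _PROTOCOL:
            cells.append(element.protocol_name)
        elif col.part == _DATE:
            cells.append(element.date or "")
        elif col.part == _PERFORMER:
            cells.append(element.performer or "")
        else:
            cells.append(_attr_cell(_find_attr(element, col.kind, col.category), col.part))
    return "\t".join(escape_field(cell) for cell in cells) + LINE_ENDING


def check_signature_match(row: TableRow, sig: HeaderSignature) -> None:
    """Raise :class:`RowStructureError` if the row's layout differs from ``sig``."""
    derived = derive_header(row)
    if derived.columns == sig.columns:
        return
    for i, (expected, got) in enumerate(zip(sig.columns, derived.columns)):
        if expected != got:
            raise RowStructureError(
                f"row structure drift at column {i}: frozen header has "
                f"{expected.header_text!r}, this row yields {got.header_text!r}",
                column_index=i,
            )
    i = min(len(sig.columns), len(derived.columns))
    if len(derived.columns) > len(sig.columns):
        extra = derived.columns[i].header_text
        raise RowStructureError(
            f"row structure drift at column {i}: row adds column {extra!r} beyond the "
            "frozen header",
            column_index=i,
        )
    missing = sig.columns[i].header_text
    raise RowStructureError(
        f"row structure drift at column {i}: row is missing column {missing!r}",
        column_index=i,
    )


@dataclass(frozen=True)
class WriteStats:
    rows_written: int
    bytes_written: int


class NullSink:
    """A discarding sink that still counts characters; used by the benchmark harness."""

    def __init__(self) -> None:
        self.chars_written = 0

    def write(self, text: str) -> int:
        self.chars_written += len(text)
        return len(text)

    def flush(self) -> None:
        pass


class DigestSink:
    """A sink that feeds written text (UTF-8) into a hash instead of storing it.

    Demonstrates the piping contract: the byte stream a file sink would
    receive can equally be checksummed on the fly.
    """

    def __init__(self, algorithm: str = "sha256") -> None:
        self._hash = hashlib.new(algorithm)

    def write(self, text: str) -> int:
        data = text.encode("utf-8")
        self._hash.update(data)
        return len(text)

    def flush(self) -> None:
        pass

    def hexdigest(self) -> str:
        return self._hash.hexdigest()


class TableStream:
    """A live table being streamed to a sink.

    Created by :func:`open_table`.  The first :meth:`write_row` derives and
    writes the header; every later row must match that frozen signature.  The
    stream never retains a reference to a written row.  Usable as a context
    manager (``finish`` on exit).
    """

    def __init__(self, sink, owns_sink: bool) -> None:
        self._sink = sink
        self._owns_sink = owns_sink
        self._finished = False
        self.signature: Optional[HeaderSignature] = None
        self.rows_written = 0
        self.bytes_written = 0

    def _emit(self, text: str) -> None:
        self._sink.write(text)
        self.bytes_written += len(text.encode("utf-8"))

    def write_row(self, row: TableRow) -> "TableStream":
        """Write one row; on the first call, write the header line first.

        A row whose structure drifts from the frozen header raises
        :class:`RowStructureError` before anything is emitted, so the file
        holds only conforming rows and no partial line.  The stream remains
        usable for conforming rows afterwards.
        """
        if self._finished:
            raise StreamStateError("cannot write to a finished stream")
        if self.signature is None:
            sig = derive_header(row)
            line = render_row_line(row, sig)  # render before emitting the header
            self._emit(render_header_line(sig))
            self.signature = sig
        else:
            line = render_row_line(row, self.signature)
        self._emit(line)
        self.rows_written += 1
        return self

    def write_rows(self, rows: Iterable[TableRow]) -> "TableStream":
        for row in rows:
            self.write_row(row)
        return self

    def finish(self) -> WriteStats:
        """Flush (and close, if the stream opened the sink itself) and return counters."""
        if self._finished:
            raise StreamStateError("stream already finished")
        self._finished = True
        flush = getattr(self._sink, "flush", None)
        if flush is not None:
            flush()
        if self._owns_sink:
            self._sink.close()
        return WriteStats(rows_written=self.rows_written, bytes_written=self.bytes_written)

    def __enter__(self) -> "TableStream":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if not self._finished:
            self.finish()


def resolve_sink(sink: Union[str, os.PathLike, io.TextIOBase, object]):
    """Return ``(writable, owns)``: open a path (owned) or accept a sink object.

    Raises :class:`OSError` for objects without a callable ``write`` or
    already-closed sinks.
    """
    if isinstance(sink, (str, os.PathLike)):
        return open(sink, "w", encoding="utf-8", newline=""), True
    write = getattr(sink, "write", None)
    if write is None or not callable(write):
        raise OSError(f"sink {sink!r} has no write method")
    if getattr(sink, "closed", False):
        raise OSError("sink is closed")
    return sink, False


def open_table(sink: Union[str, os.PathLike, io.TextIOBase, object]) -> TableStream:
    """Open a table stream on a path or writable text sink.

    A path argument opens (and truncates) the file in UTF-8 without BOM and
    the stream owns it: :meth:`TableStream.finish` closes it.  A sink object
    handed in by the caller is only flushed, never closed, so it can be piped
    onward (checksumming, compression, an HTTP response...).
    """
    handle, owns = resolve_sink(sink)
    return TableStream(handle, owns_sink=owns)
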