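"""Streaming table writer: header derivation, escaping, freeze semantics, sinks."""

import csv
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isatabstream import (
    AttributeKind,
    AttributeValue,
    DigestSink,
    MetadataNode,
    NodeRole,
    OntologyAnnotation,
    ProcessStep,
    RowStructureError,
    StreamStateError,
    TableRow,
    derive_header,
    escape_field,
    open_table,
    render_header_line,
    render_row_line,
)
from conftest import parse_cells, render_to_string


class TestDeriveHeader:
    def test_minimal_chain_headers(self, minimal_row):
        assert derive_header(minimal_row).header_texts == (
            "Source Name",
            "Protocol REF",
            "Sample Name",
        )

    def test_annotated_characteristic_expands_to_three_columns(self, annotated_sample_row):
        assert derive_header(annotated_sample_row).header_texts == (
            "Source Name",
            "Protocol REF",
            "Sample Name",
            "Characteristics[Organism]",
            "Term Source REF",
            "Term Accession Number",
        )

    def test_unit_with_annotation_expands_after_unit(self):
        sample = MetadataNode(
            NodeRole.SAMPLE,
            "sm",
            [
                AttributeValue(
                    AttributeKind.CHARACTERISTIC,
                    "Height",
                    "12",
                    unit=OntologyAnnotation("centimeter", "obo:UO_0000015", "UO"),
                )
            ],
        )
        row = TableRow([MetadataNode(NodeRole.SOURCE, "s"), ProcessStep("p"), sample])
        assert derive_header(row).header_texts[3:] == (
            "Characteristics[Height]",
            "Unit",
            "Term Source REF",
            "Term Accession Number",
        )

    def test_process_date_performer_and_comment_columns(self):
        process = ProcessStep(
            "imaging",
            [
                AttributeValue(AttributeKind.PARAMETER_VALUE, "Exposure", "2"),
                AttributeValue(AttributeKind.COMMENT, "Note", "ok"),
            ],
            date="2020-01-01",
            performer="robot",
        )
        row = TableRow(
            [
                MetadataNode(NodeRole.SAMPLE, "sm"),
                process,
                MetadataNode(NodeRole.IMAGE_FILE, "img.png"),
            ]
        )
        assert derive_header(row).header_texts == (
            "Sample Name",
            "Protocol REF",
            "Parameter Value[Exposure]",
            "Date",
            "Performer",
            "Comment[Note]",
            "Image File",
        )

    def test_equal_rows_yield_equal_signatures(self, annotated_sample_row):
        sample = MetadataNode(
            NodeRole.SAMPLE,
            "other",
            [
                AttributeValue(
                    AttributeKind.CHARACTERISTIC,
                    "Organism",
                    OntologyAnnotation("Zea mays", "obo:NCBITaxon_4577", "NCBITAXON"),
                )
            ],
        )
        other = TableRow(
            [MetadataNode(NodeRole.SOURCE, "x"), ProcessStep("other"), sample]
        )
        assert derive_header(other) == derive_header(annotated_sample_row)


class TestEscaping:
    @pytest.mark.parametrize(
        "value,expected",
        [
            ("plain", "plain"),
            ("a\tb", '"a\tb"'),
            ('say "hi"', '"say ""hi"""'),
            ("line\nbreak", '"line\nbreak"'),
            ("", ""),
        ],
    )
    def test_escape_examples(self, value, expected):
        assert escape_field(value) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=st.characters(codec="utf-8"), max_size=40))
    def test_escape_round_trips_through_standard_reader(self, value):
        line = "\t".join([escape_field(value), escape_field("other")]) + "\n"
        parsed = next(csv.reader(io.StringIO(line), delimiter="\t", quotechar='"'))
        assert parsed[0] == value

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.text(alphabet=st.characters(codec="utf-8"), max_size=20),
            min_size=2,  # writer lines always span >= 3 columns, never one lone cell
            max_size=6,
        )
    )
    def test_column_count_conserved_for_any_cell_contents(self, cells):
        line = "\t".join(escape_field(c) for c in cells) + "\n"
        parsed = next(csv.reader(io.StringIO(line), delimiter="\t", quotechar='"'))
        assert parsed == cells


class TestRenderLines:
    def test_header_line_joins_with_tabs(self, minimal_row):
        sig = derive_header(minimal_row)
        assert render_header_line(sig) == "Source Name\tProtocol REF\tSample Name\n"

    def test_row_line_in_signature_order(self, minimal_row):
        sig = derive_header(minimal_row)
        assert render_row_line(minimal_row, sig) == "s1\tsampling\tsm1\n"

    def test_empty_accession_keeps_cell_present(self):
        sample = MetadataNode(
            NodeRole.SAMPLE,
            "sm",
            [
                AttributeValue(
                    AttributeKind.CHARACTERISTIC,
                    "Organism",
                    OntologyAnnotation("barley"),  # no accession, no source
                )
            ],
        )
        row = TableRow([MetadataNode(NodeRole.SOURCE, "s"), ProcessStep("p"), sample])
        line = render_row_line(row, derive_header(row))
        assert line == "s\tp\tsm\tbarley\t\t\n"

    def test_row_missing_attribute_is_structure_error(self, minimal_row, annotated_sample_row):
        sig = derive_header(annotated_sample_row)
        with pytest.raises(RowStructureError) as exc:
            render_row_line(minimal_row, sig)
        assert "Characteristics[Organism]" in str(exc.value)


class TestTableStream:
    def test_header_written_once_then_rows(self, minimal_row):
        text = render_to_string([minimal_row, minimal_row])
        assert text.splitlines() == [
            "Source Name\tProtocol REF\tSample Name",
            "s1\tsampling\tsm1",
            "s1\tsampling\tsm1",
        ]

    def test_structure_drift_rejected_and_stream_still_usable(
        self, minimal_row, annotated_sample_row
    ):
        buf = io.StringIO()
        stream = open_table(buf)
        stream.write_row(minimal_row)
        with pytest.raises(RowStructureError):
            stream.write_row(annotated_sample_row)
        stream.write_row(minimal_row)  # conforming rows still accepted
        stats = stream.finish()
        assert stats.rows_written == 2
        assert len(buf.getvalue().splitlines()) == 3  # no partial line emitted

    def test_drift_error_names_first_differing_column(self, minimal_row):
        assay_row = TableRow(
            [
                MetadataNode(NodeRole.SAMPLE, "sm"),
                ProcessStep("p"),
                MetadataNode(NodeRole.RAW_DATA_FILE, "f.txt"),
            ]
        )
        buf = io.StringIO()
        stream = open_table(buf)
        stream.write_row(minimal_row)
        with pytest.raises(RowStructureError) as exc:
            stream.write_row(assay_row)
        assert exc.value.column_index == 0
        assert "Source Name" in str(exc.value)

    def test_finish_counts_and_double_finish(self, minimal_row):
        buf = io.StringIO()
        stream = open_table(buf)
        stream.write_row(minimal_row).write_row(minimal_row)
        stats = stream.finish()
        assert stats.rows_written == 2
        assert stats.bytes_written == len(buf.getvalue().encode("utf-8"))
        with pytest.raises(StreamStateError):
            stream.finish()

    def test_finish_with_zero_rows_gives_empty_output(self):
        buf = io.StringIO()
        stats = open_table(buf).finish()
        assert stats.rows_written == 0 and buf.getvalue() == ""

    def test_write_after_finish_rejected(self, minimal_row):
        stream = open_table(io.StringIO())
        stream.finish()
        with pytest.raises(StreamStateError):
            stream.write_row(minimal_row)

    def test_open_on_closed_sink_raises(self):
        buf = io.StringIO()
        buf.close()
        with pytest.raises(OSError):
            open_table(buf)

    def test_path_sink_owned_and_closed(self, tmp_path, minimal_row):
        path = tmp_path / "s_test.txt"
        stream = open_table(path)
        stream.write_row(minimal_row)
        stream.finish()
        assert path.read_text(encoding="utf-8").startswith("Source Name\t")

    def test_caller_sink_is_not_closed(self, minimal_row):
        buf = io.StringIO()
        with open_table(buf) as stream:
            stream.write_row(minimal_row)
        assert not buf.closed

    def test_sink_agnosticism_file_buffer_and_digest_agree(self, tmp_path, minimal_row):
        import hashlib

        rows = [minimal_row] * 4
        path = tmp_path / "s_x.txt"
        stream = open_table(path)
        for row in rows:
            stream.write_row(row)
        stream.finish()
        file_digest = hashlib.sha256(path.read_bytes()).hexdigest()

        text = render_to_string(rows)
        buffer_digest = hashlib.sha256(text.encode("utf-8")).hexdigest()

        digest_sink = DigestSink("sha256")
        stream = open_table(digest_sink)
        for row in rows:
            stream.write_row(row)
        stream.finish()

        assert file_digest == buffer_digest == digest_sink.hexdigest()

    def test_output_parses_back_cell_by_cell(self, annotated_sample_row):
        text = render_to_string([annotated_sample_row])
        cells = parse_cells(text)
        assert cells[1] == [
            "s1",
            "sampling",
            "sm1",
            "Hordeum vulgare",
            "NCBITAXON",
            "obo:NCBITaxon_4513",
        ]
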