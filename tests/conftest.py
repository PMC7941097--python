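import io
from pathlib import Path

import pytest

from isatabstream import (
    AttributeKind,
    AttributeValue,
    MetadataNode,
    NodeRole,
    OntologyAnnotation,
    ProcessStep,
    TableRow,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def minimal_row() -> TableRow:
    return TableRow(
        [
            MetadataNode(NodeRole.SOURCE, "s1"),
            ProcessStep("sampling"),
            MetadataNode(NodeRole.SAMPLE, "sm1"),
        ]
    )


@pytest.fixture
def annotated_sample_row() -> TableRow:
    sample = MetadataNode(
        NodeRole.SAMPLE,
        "sm1",
        [
            AttributeValue(
                AttributeKind.CHARACTERISTIC,
                "Organism",
                OntologyAnnotation("Hordeum vulgare", "obo:NCBITaxon_4513", "NCBITAXON"),
            )
        ],
    )
    return TableRow([MetadataNode(NodeRole.SOURCE, "s1"), ProcessStep("sampling"), sample])


def render_to_string(rows) -> str:
    """Stream rows into an in-memory buffer and return the text."""
    from isatabstream import open_table

    buf = io.StringIO()
    stream = open_table(buf)
    for row in rows:
        stream.write_row(row)
    stream.finish()
    return buf.getvalue()


def parse_cells(text: str) -> list[list[str]]:
    """Parse tab-separated text with the declared quoting dialect."""
    import csv

    return list(csv.reader(io.StringIO(text), delimiter="\t", quotechar='"'))
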