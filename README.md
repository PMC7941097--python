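# isatab-stream

A Python library and CLI for generating **ISA-Tab** experimental metadata —
one investigation file (`i_*.txt`) plus tab-separated study (`s_*.txt`) and
assay (`a_*.txt`) tables — from an in-memory object model, with a
**streaming, constant-memory** table writer.

## Who this is for

The Investigation–Study–Assay (ISA) framework gives experimental metadata a
machine-readable, plain-text structure, so that published data is findable,
accessible, interoperable and reusable (FAIR). Communities such as plant
phenotyping (MIAPPE) layer their standards on it. When metadata is produced
programmatically — exporting thousands of samples from a LIMS or database —
the writer should not need to hold the whole table in memory or re-infer the
column layout from an arbitrary object soup.

`isatab-stream` takes the opposite trade: the column layout of a table is
**derived from the first row and frozen**. After the header is written, each
row is rendered, flushed to the sink, and dropped; memory use is independent
of the number of rows, so tables bigger than RAM are fine and the output can
be piped straight into a checksum, a compressor, or an HTTP response. A row
whose structure would require different columns is an error, never a silent
widening — headers cannot be modified once written.

## The model in brief

A table row is one path through the experimental provenance graph: an
alternating chain of *nodes* (Source, Sample, Extract, Raw Data File, …) and
*processes* (applications of a named protocol, rendered as `Protocol REF`).
Nodes and processes carry ordered, typed attributes — `Characteristics[c]`,
`Factor Value[f]`, `Parameter Value[p]`, `Comment[c]` — and any value may be
ontology-annotated, expanding into the value column followed by
`Term Source REF` and `Term Accession Number`. Investigation-level entities
(ontology sources, publications, contacts, studies, assays, protocols)
render into the vertical block layout of the investigation file.

## Worked example

```python
import io
from isatabstream import (
    AttributeKind, AttributeValue, MetadataNode, NodeRole,
    OntologyAnnotation, ProcessStep, TableRow, open_table,
)

sample = MetadataNode(NodeRole.SAMPLE, "sample_0", [
    AttributeValue(
        AttributeKind.CHARACTERISTIC, "Organism",
        OntologyAnnotation("Hordeum vulgare",
                           "http://purl.obolibrary.org/obo/NCBITaxon_4513",
                           "NCBITAXON"),
    ),
])
row = TableRow([
    MetadataNode(NodeRole.SOURCE, "source_0"),
    ProcessStep("sample collection"),
    sample,
])

buf = io.StringIO()
stream = open_table(buf)          # a path works too; files the stream opens, it closes
stream.write_row(row)             # first row freezes the header
print(stream.finish())            # WriteStats(rows_written=1, bytes_written=...)
print(buf.getvalue())
```

prints

```
WriteStats(rows_written=1, bytes_written=209)
Source Name	Protocol REF	Sample Name	Characteristics[Organism]	Term Source REF	Term Accession Number
source_0	sample collection	sample_0	Hordeum vulgare	NCBITAXON	http://purl.obolibrary.org/obo/NCBITaxon_4513
```

The header line shows the frozen layout derived from the row: one name
column per node, `Protocol REF` per process, and the annotated
characteristic expanded into three columns. The stats confirm one data row
was streamed and how many bytes reached the sink.

### CLI

```bash
isatab-stream write --config config.yaml --out outdir/   # i_/s_/a_ files from YAML + TSV rows
isatab-stream bench --level minimal --rows 100,10000 --reps 5 --out bench.csv
```

`write` renders an investigation described in YAML, streaming study/assay
rows from tab-separated input files through a chain template (see
`isatabstream/config.py` for the format). `bench` measures CPU time and
baseline-subtracted peak memory versus row count at three fixture
complexity levels — `minimal` (6 columns across study+assay), `reduced`
(11), and `real_world_like` (119 by default, parameterizable) — and writes
a CSV of measurements.

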