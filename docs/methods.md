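# Methods

## Serialization model

A study or assay table is written row by row. The first row handed to a
`TableStream` determines the complete column layout (the *header
signature*): for each node in the row's chain, the role's name column
(`Source Name`, `Sample Name`, `Extract Name`, `Raw Data File`, …), then its
characteristics, factor values and comments in insertion order; for each
process, `Protocol REF`, its parameter values, then `Date` and `Performer`
when set, then comments. An ontology-annotated value expands with
`Term Source REF` and `Term Accession Number` columns; a unit appends `Unit`
(plus the two term columns again when the unit itself is annotated). The
signature is frozen once the header line is written: every subsequent row is
re-derived and compared column by column, and a mismatch raises an error
*before* any cell of that row is emitted, so the file only ever contains
complete, conforming lines. This is the whole trade of the design — the
writer never buffers rows or infers a layout from a completed graph, so
memory use does not depend on row count, at the price that callers must
structure rows consistently.

Assumptions worth stating:

- Each row is one complete path through the provenance graph. Repeated node
  names across rows imply sharing only semantically; the writer does not
  merge, reorder, or pool rows.
- Factor values are a sample-context concept and are rejected on source and
  material nodes; parameter values live only on processes. Within one node
  or process a `(kind, category)` pair is unique.
- A value that carries a unit is plain text (typically numeric) and the unit
  may be ontology-annotated; a value cannot be both annotated and carry a
  unit, which mirrors the column grammar (value, `Unit`, term columns).

## Dialect and numerical choices

- Output is UTF-8 without BOM, LF line endings, tab-separated. A field
  containing a tab, newline, carriage return or double quote is wrapped in
  double quotes with internal quotes doubled; this round-trips through
  standard delimited-text readers (`csv` with `delimiter='\t'`,
  `quotechar='"'`). Empty optional cells (e.g. a missing accession) are
  emitted as empty fields, never dropped, so every line has exactly as many
  fields as the header.
- The investigation file renders whole (it is small) in the fixed block
  order of the ISA-Tab v1.0 specification, including empty blocks as
  label-plus-empty-field rows; ontology-annotated investigation fields
  expand to value / `Term Accession Number` / `Term Source REF` field rows.
  Multi-value cells (protocol parameter lists, contact roles) are packed
  with `;` and no surrounding spaces.
- Streams close sinks they opened themselves (paths) and only flush sinks
  the caller handed in, so callers can pipe the character stream into
  checksumming or compression.
- Referential issues (undeclared protocol or ontology-source references) are
  warnings from `validate_investigation`; only duplicate study/assay
  filenames are fatal at render time. Strict semantic validation belongs to
  downstream validators. Dates are carried as ISO-8601 text, unvalidated
  beyond being text, as the format itself stores them.

## Fixture generators

Three deterministic complexity levels drive the tests and the benchmark;
all names and values are pure functions of the row index, and rows are
yielded lazily.

| level | study row | assay row | columns |
|---|---|---|---|
| `minimal` | Source → Process → Sample | Sample → Process → Raw Data File | 3 + 3 = 6 |
| `reduced` | minimal + one annotated Characteristic on the Sample | minimal + intermediary Extract with its own `Protocol REF` | 6 + 5 = 11 |
| `real_world_like` | wide, MIAPPE-style | wide, MIAPPE-style | 87 + 32 = 119 (default shape) |

The reduced layout is the natural widening consistent with an 11-column
total: the annotated characteristic adds three study columns and the
intermediary material adds `Extract Name` plus a second `Protocol REF` to
the assay file. The wide level is parameterized
(`RealWorldShape`: counts of source/sample characteristics, factor values,
parameter values per process, comments); the default shape approximates the
width of published MIAPPE-compliant plant-phenotyping metadata at 119
columns but is a parameterized emulation, not a byte-level clone of any
dataset. What the generators do **not** emulate about real data: shared or
pooled samples across rows, missing values, heterogeneous row structures
within one file, realistic vocabulary distributions. Passing tests on these
fixtures demonstrate the writer's structural and scaling behaviour, not
semantic fidelity to any particular experiment.

## Benchmark protocol

`run_benchmark` first writes a warm-up batch (default 100 wide rows) to a
discarding sink, forces garbage collection, and records a memory baseline;
each measurement then writes n study and n assay rows to discarding sinks,
recording process CPU time (`time.process_time`) and peak traced allocation
(`tracemalloc`) minus the baseline — isolating the memory consumed by table
content from interpreter and library periphery. Allocation tracing itself
costs CPU, so CPU-focused runs pass `trace_memory=False` and memory and CPU
are measured in separate runs. Absolute seconds and bytes are hardware- and
runtime-specific; assertions are made on ratios only: peak memory streaming
10^5 minimal rows must stay within 2× of 10^3 rows, and median CPU time at
10^5 rows must fall between 5× and 20× the median at 10^4 rows (a loose band
tolerating constant overheads around the linear regime). These problem sizes
keep a full suite run around half a minute on one CPU while sitting well
inside the linear-scaling regime, which starts at a few hundred rows.

## Reference comparison

The expected renderings of the minimal and reduced fixtures (3 rows each)
were hand-derived from the ISA-Tab v1.0 table column grammar and frozen as
synthetic reference tables under `tests/data/`; equivalence is asserted
cell-by-cell after parsing with a standard tab-delimited reader, so the
check is independent of incidental dialect bytes. The investigation output
is checked against the block grammar (label rows, field-label prefixes,
block order) rather than against any external tool.

## Known limitations

- No parsing of ISA-Tab back into the model, no ISA-JSON, and no semantic
  validation against ontology term lists.
- One `TableRow` per output line; branching/pooling graphs must be flattened
  into paths by the caller.
- The header-freeze contract means optional attributes must be present (with
  empty values where unknown) from the first row onward.
- `tracemalloc` tracks Python-level allocations only; memory consumed
  outside the allocator (e.g. by the OS file cache) is invisible to the
  harness, which is acceptable because only ratios are interpreted.
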