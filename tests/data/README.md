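# Synthetic reference tables

These four files are *synthetic reference* renderings of the minimal and
reduced fixture graphs (n = 3 rows), hand-derived directly from the ISA-Tab
v1.0 table column grammar — node name column, `Protocol REF` per process,
`Characteristics[...]` followed by `Term Source REF` and
`Term Accession Number` for an ontology-annotated value.  They were written
out by hand from the format rules, independently of the package's serializer,
and serve as the expected side of cell-by-cell equivalence tests.
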