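"""Deterministic row generators at three complexity levels.

These generators emulate the scaling study the package is built around:
writing n study rows and n assay rows at increasing structural width.

* ``minimal`` — the narrowest well-formed layout: the study row links a
  Source through one Process to a Sample, the assay row links that Sample
  through one Process to a raw data file, with no attributes anywhere.
  Study and assay headers have 3 fields each — 6 columns in total.
* ``reduced`` — minimal plus one ontology-annotated Characteristic on the
  study Sample (3 extra study columns) and an intermediary extract Material
  with its own Protocol REF in the assay chain (2 extra assay columns) —
  11 columns in total.
* ``real_world_like`` — wide rows shaped like MIAPPE-style plant-phenotyping
  metadata, with parameterizable counts of characteristics, factor values,
  parameter values and comments.  The default shape yields 119 columns
  across both files, approximating the width of published real-world
  phenotyping metadata; the layout is parameterized, not a byte-level clone
  of any particular dataset.

All names and values are pure functions of the row index: two calls with
equal arguments produce equal row sequences, and rows are yielded lazily so
arbitrarily large tables can be streamed without materialising a list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

from .errors import InvalidArgumentError
from .model import (
    Assay,
    AttributeKind,
    AttributeValue,
    Investigation,
    MetadataNode,
    NodeRole,
    OntologyAnnotation,
    OntologySourceReference,
    ProcessStep,
    ProtocolDefinition,
    Study,
    TableRow,
)

__all__ = [
    "ComplexityLevel",
    "MINIMAL",
    "REDUCED",
    "REAL_WORLD_LIKE",
    "RealWorldShape",
    "build_investigation",
    "gen_rows",
    "get_level",
    "real_world_like",
]

_ORGANISM = OntologyAnnotation(
    term="Hordeum vulgare",
    accession="http://purl.obolibrary.org/obo/NCBITaxon_4513",
    source_name="NCBITAXON",
)

_EXAMPLE_SOURCE = "EXO"  # term source name used by generated wide-row annotations


@dataclass(frozen=True)
class ComplexityLevel:
    """A named complexity level with a deterministic per-index row factory."""

    name: str
    row_factory: Callable[[int], tuple[TableRow, TableRow]]
    #: protocol names used by the rows, in study-file then assay-file order
    study_protocols: tuple[str, ...] = ()
    assay_protocols: tuple[str, ...] = ()
    ontology_sources: tuple[OntologySourceReference, ...] = ()


def _minimal_rows(i: int) -> tuple[TableRow, TableRow]:
    study_row = TableRow(
        [
            MetadataNode(NodeRole.SOURCE, f"source_{i}"),
            ProcessStep("sample collection"),
            MetadataNode(NodeRole.SAMPLE, f"sample_{i}"),
        ]
    )
    assay_row = TableRow(
        [
            MetadataNode(NodeRole.SAMPLE, f"sample_{i}"),
            ProcessStep("data collection"),
            MetadataNode(NodeRole.RAW_DATA_FILE, f"file_{i}.txt"),
        ]
    )
    return study_row, assay_row


def _reduced_rows(i: int) -> tuple[TableRow, TableRow]:
    sample = MetadataNode(
        NodeRole.SAMPLE,
        f"sample_{i}",
        [AttributeValue(AttributeKind.CHARACTERISTIC, "Organism", _ORGANISM)],
    )
    study_row = TableRow(
        [
            MetadataNode(NodeRole.SOURCE, f"source_{i}"),
            ProcessStep("sample collection"),
            sample,
        ]
    )
    assay_row = TableRow(
        [
            MetadataNode(NodeRole.SAMPLE, f"sample_{i}"),
            ProcessStep("extraction"),
            MetadataNode(NodeRole.EXTRACT, f"extract_{i}"),
            ProcessStep("data collection"),
            MetadataNode(NodeRole.RAW_DATA_FILE, f"file_{i}.txt"),
        ]
    )
    return study_row, assay_row


@dataclass(frozen=True)
class RealWorldShape:
    """Column-width parameters for the wide, MIAPPE-style layout.

    Each annotated attribute contributes three columns (value, Term Source
    REF, Term Accession Number); each comment contributes one.  The defaults
    put 119 columns across study (87) and assay (32) files.
    """

    source_characteristics: int = 8
    growth_parameters: int = 7
    sample_characteristics: int = 8
    factor_values: int = 4
    assay_parameters: int = 8
    sample_comments: int = 2
    process_comments: int = 2
    file_comments: int = 1

    def column_count(self) -> int:
        annotated = (
            self.source_characteristics
            + self.growth_parameters
            + self.sample_characteristics
            + self.factor_values
            + self.assay_parameters
        )
        comments = self.sample_comments + self.process_comments + self.file_comments
        # fixed structural columns: 4 (study) + 5 (assay); see generator below
        return 9 + 3 * annotated + comments


def _annotated_value(prefix: str, j: int, i: int) -> OntologyAnnotation:
    return OntologyAnnotation(
        term=f"{prefix} value {i}",
        accession=f"http://example.org/{prefix.replace(' ', '_')}/{j}",
        source_name=_EXAMPLE_SOURCE,
    )


def _attrs(kind: AttributeKind, prefix: str, count: int, i: int) -> list[AttributeValue]:
    return [
        AttributeValue(kind, f"{prefix} {j + 1}", _annotated_value(prefix.lower(), j + 1, i))
        for j in range(count)
    ]


def _comments(prefix: str, count: int, i: int) -> list[AttributeValue]:
    return [
        AttributeValue(AttributeKind.COMMENT, f"{prefix} {j + 1}", f"{prefix.lower()} {i}.{j + 1}")
        for j in range(count)
    ]


def _real_world_factory(shape: RealWorldShape) -> Callable[[int], tuple[TableRow, TableRow]]:
    def factory(i: int) -> tuple[TableRow, TableRow]:
        source = MetadataNode(
            NodeRole.SOURCE,
            f"plant_{i}",
            _attrs(AttributeKind.CHARACTERISTIC, "Source Trait", shape.source_characteristics, i),
        )
        growing = ProcessStep(
            "Growth",
            _attrs(AttributeKind.PARAMETER_VALUE, "Growth Setting", shape.growth_parameters, i),
            date="2020-01-01",
        )
        sample = MetadataNode(
            NodeRole.SAMPLE,
            f"sample_{i}",
            _attrs(AttributeKind.CHARACTERISTIC, "Sample Trait", shape.sample_characteristics, i)
            + _attrs(AttributeKind.FACTOR_VALUE, "Treatment", shape.factor_values, i)
            + _comments("Sample Note", shape.sample_comments, i),
        )
        study_row = TableRow([source, growing, sample])

        phenotyping = ProcessStep(
            "Phenotyping",
            _attrs(AttributeKind.PARAMETER_VALUE, "Imaging Setting", shape.assay_parameters, i)
            + _comments("Run Note", shape.process_comments, i),
            date="2020-01-02",
            performer="imaging robot",
        )
        assay_row = TableRow(
            [
                MetadataNode(NodeRole.SAMPLE, f"sample_{i}"),
                phenotyping,
                MetadataNode(
                    NodeRole.IMAGE_FILE,
                    f"image_{i}.png",
                    _comments("File Note", shape.file_comments, i),
                ),
            ]
        )
        return study_row, assay_row

    return factory


MINIMAL = ComplexityLevel(
    name="minimal",
    row_factory=_minimal_rows,
    study_protocols=("sample collection",),
    assay_protocols=("data collection",),
)

REDUCED = ComplexityLevel(
    name="reduced",
    row_factory=_reduced_rows,
    study_protocols=("sample collection",),
    assay_protocols=("extraction", "data collection"),
    ontology_sources=(
        OntologySourceReference(
            name="NCBITAXON",
            file="http://purl.obolibrary.org/obo/ncbitaxon.owl",
            version="2020",
            description="NCBI organismal taxonomy",
        ),
    ),
)


def real_world_like(shape: RealWorldShape = RealWorldShape()) -> ComplexityLevel:
    """Build the wide complexity level for a given (default 119-column) shape."""
    return ComplexityLevel(
        name="real_world_like",
        row_factory=_real_world_factory(shape),
        study_protocols=("Growth",),
        assay_protocols=("Phenotyping",),
        ontology_sources=(
            OntologySourceReference(
                name=_EXAMPLE_SOURCE,
                file="http://example.org/exo.owl",
                version="1",
                description="synthetic example ontology used by generated wide rows",
            ),
        ),
    )


REAL_WORLD_LIKE = real_world_like()

_LEVELS = {level.name: level for level in (MINIMAL, REDUCED, REAL_WORLD_LIKE)}


def get_level(name: str) -> ComplexityLevel:
    try:
        return _LEVELS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown complexity level {name!r}; choose from {sorted(_LEVELS)}"
        ) from None


def gen_rows(level: ComplexityLevel, n: int) -> Iterator[tuple[TableRow, TableRow]]:
    """Lazily yield exactly ``n`` (study row, assay row) pairs for ``level``.

    Pure and deterministic: names are functions of the index alone.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    return (level.row_factory(i) for i in range(n))


def build_investigation(level: ComplexityLevel) -> Investigation:
    """A minimal well-formed investigation (1 study, 1 assay) matching ``level``.

    Declares every ontology source and protocol the level's rows use, so
    :func:`isatabstream.model.validate_investigation` returns no issues.
    """
    protocols = [
        ProtocolDefinition(name=name)
        for name in dict.fromkeys(level.study_protocols + level.assay_protocols)
    ]
    study = Study(
        identifier=f"{level.name}_study",
        filename=f"s_{level.name}.txt",
        title=f"Synthetic {level.name} scaling study",
        description=f"Deterministic fixture rows at the {level.name} complexity level.",
        protocols=protocols,
        assays=[
            Assay(
                filename=f"a_{level.name}.txt",
                measurement_type=OntologyAnnotation(term="phenotyping"),
                technology_type=OntologyAnnotation(term="data transformation"),
            )
        ],
    )
    return Investigation(
        identifier=f"{level.name}_investigation",
        title=f"Synthetic {level.name} fixture investigation",
        description="Generated for scaling measurements and tests.",
        ontology_sources=list(level.ontology_sources),
        studies=[study],
    )
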