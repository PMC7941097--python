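"""In-memory ISA object model.

The Investigation–Study–Assay (ISA) framework describes an experiment as an
investigation that groups studies, each study grouping the subjects and
treatments applied to them, and each assay documenting one measurement
technology applied to study samples.  Table files (study and assay) record
one path through the experimental provenance graph per row: an alternating
chain of materials (source, sample, extract, data file, ...) and processes
(applications of a named protocol).  This module holds the object model for
both the investigation-level entities and the table-row building blocks;
serialization lives in :mod:`isatabstream.streaming` and
:mod:`isatabstream.investigation`.

Attributes attached to nodes and processes — characteristics, factor values,
parameter values, comments — render as bracketed columns (for example
``Characteristics[Organism]``), and any of them may carry an ontology
annotation linking the value to an established vocabulary, rendered as the
value column followed by ``Term Source REF`` and ``Term Accession Number``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

from .errors import (
    DuplicateAttributeError,
    InvalidArgumentError,
    RoleError,
    StructureError,
)

__all__ = [
    "AttributeKind",
    "AttributeValue",
    "Assay",
    "Investigation",
    "MetadataNode",
    "NodeRole",
    "OntologyAnnotation",
    "OntologySourceReference",
    "Person",
    "ProcessStep",
    "ProtocolDefinition",
    "Publication",
    "Study",
    "StudyFactor",
    "TableRow",
    "make_ontology_annotation",
    "validate_investigation",
]

_FORBIDDEN_IN_NAMES = ("\t", "\n", "\r")


def _check_no_control(text: str, what: str) -> None:
    if any(ch in text for ch in _FORBIDDEN_IN_NAMES):
        raise InvalidArgumentError(f"{what} must not contain tab or newline characters: {text!r}")


@dataclass(frozen=True)
class OntologySourceReference:
    """A declared terminology source (e.g. the Plant Ontology), listed once per investigation."""

    name: str
    file: str = ""
    version: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidArgumentError("ontology source name must be non-empty")
        _check_no_control(self.name, "ontology source name")


@dataclass(frozen=True)
class OntologyAnnotation:
    """A vocabulary term with an optional accession (IRI/CURIE) and term-source name.

    In table files an annotated value expands to three columns: the value
    itself, ``Term Source REF`` and ``Term Accession Number``.  Either of the
    latter two may be empty text; the columns are still emitted.
    """

    term: str
    accession: str = ""
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.term:
            raise InvalidArgumentError("ontology annotation term must be non-empty")


def make_ontology_annotation(term: str, accession: str = "", source_name: str = "") -> OntologyAnnotation:
    """Build an :class:`OntologyAnnotation`; raises on empty ``term``."""
    return OntologyAnnotation(term=term, accession=accession, source_name=source_name)


class AttributeKind(str, Enum):
    """Which bracketed column family an attribute renders into."""

    CHARACTERISTIC = "characteristic"
    FACTOR_VALUE = "factor_value"
    PARAMETER_VALUE = "parameter_value"
    COMMENT = "comment"

    @property
    def header_prefix(self) -> str:
        return {
            AttributeKind.CHARACTERISTIC: "Characteristics",
            AttributeKind.FACTOR_VALUE: "Factor Value",
            AttributeKind.PARAMETER_VALUE: "Parameter Value",
            AttributeKind.COMMENT: "Comment",
        }[self]


@dataclass(frozen=True)
class AttributeValue:
    """One typed attribute: a category label plus a value, optionally with a unit.

    A value is either plain text or an :class:`OntologyAnnotation`.  A value
    carrying a unit is treated as plain text (typically numeric) and the unit
    itself may be ontology-annotated; a value may not simultaneously be an
    ontology annotation and carry a unit — this mirrors the table column
    grammar (value, ``Unit``, then the unit's term columns).
    """

    kind: AttributeKind
    category: str
    value: Union[str, OntologyAnnotation] = ""
    unit: Optional[Union[str, OntologyAnnotation]] = None

    def __post_init__(self) -> None:
        if not self.category:
            raise InvalidArgumentError("attribute category must be non-empty")
        _check_no_control(self.category, "attribute category")
        if "[" in self.category or "]" in self.category:
            raise InvalidArgumentError(
                f"attribute category must not contain square brackets: {self.category!r}"
            )
        if self.unit is not None and isinstance(self.value, OntologyAnnotation):
            raise InvalidArgumentError(
                "a value may carry a unit or be an ontology annotation, not both"
            )
        if not isinstance(self.kind, AttributeKind):
            raise InvalidArgumentError(f"unknown attribute kind: {self.kind!r}")


class NodeRole(str, Enum):
    """The material/data role of a node, determining its name-column header."""

    SOURCE = "source"
    SAMPLE = "sample"
    MATERIAL = "material"
    EXTRACT = "extract"
    LABELED_EXTRACT = "labeled_extract"
    RAW_DATA_FILE = "raw_data_file"
    DERIVED_DATA_FILE = "derived_data_file"
    IMAGE_FILE = "image_file"

    @property
    def name_header(self) -> str:
        return {
            NodeRole.SOURCE: "Source Name",
            NodeRole.SAMPLE: "Sample Name",
            NodeRole.MATERIAL: "Material Name",
            NodeRole.EXTRACT: "Extract Name",
            NodeRole.LABELED_EXTRACT: "Labeled Extract Name",
            NodeRole.RAW_DATA_FILE: "Raw Data File",
            NodeRole.DERIVED_DATA_FILE: "Derived Data File",
            NodeRole.IMAGE_FILE: "Image File",
        }[self]


_NODE_KINDS = {
    # factor values are a sample-context concept; everything else is broadly allowed
    NodeRole.SOURCE: {AttributeKind.CHARACTERISTIC, AttributeKind.COMMENT},
    NodeRole.SAMPLE: {AttributeKind.CHARACTERISTIC, AttributeKind.FACTOR_VALUE, AttributeKind.COMMENT},
    NodeRole.MATERIAL: {AttributeKind.CHARACTERISTIC, AttributeKind.COMMENT},
    NodeRole.EXTRACT: {AttributeKind.CHARACTERISTIC, AttributeKind.COMMENT},
    NodeRole.LABELED_EXTRACT: {AttributeKind.CHARACTERISTIC, AttributeKind.COMMENT},
    NodeRole.RAW_DATA_FILE: {AttributeKind.COMMENT},
    NodeRole.DERIVED_DATA_FILE: {AttributeKind.COMMENT},
    NodeRole.IMAGE_FILE: {AttributeKind.COMMENT},
}


class _AttributeHolder:
    """Shared duplicate/ordering logic for nodes and processes."""

    attributes: list  # set by subclasses

    def _permitted(self, kind: AttributeKind) -> bool:
        raise NotImplementedError

    def add_attribute(self, attribute: AttributeValue) -> "_AttributeHolder":
        """Append an attribute, preserving insertion order.

        Raises :class:`DuplicateAttributeError` if an attribute with the same
        (kind, category) is already present, and :class:`RoleError` if the
        kind is not permitted here (e.g. a factor value on a source node).
        Returns ``self`` so calls can be chained.
        """
        if not self._permitted(attribute.kind):
            raise RoleError(
                f"attribute kind {attribute.kind.value!r} is not permitted on {self!r}"
            )
        for existing in self.attributes:
            if (existing.kind, existing.category) == (attribute.kind, attribute.category):
                raise DuplicateAttributeError(
                    f"duplicate attribute ({attribute.kind.value}, {attribute.category!r})"
                )
        self.attributes.append(attribute)
        return self


@dataclass
class MetadataNode(_AttributeHolder):
    """A named node of the provenance graph carrying ordered attributes.

    The name may be empty text (the cell renders empty) but the name column
    is always emitted: column presence is structural, not data-dependent.
    """

    node_role: NodeRole
    name: str = ""
    attributes: list[AttributeValue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.node_role, NodeRole):
            self.node_role = NodeRole(self.node_role)
        seen: set[tuple[AttributeKind, str]] = set()
        for attr in self.attributes:
            if attr.kind not in _NODE_KINDS[self.node_role]:
                raise RoleError(
                    f"attribute kind {attr.kind.value!r} is not permitted on a "
                    f"{self.node_role.value} node"
                )
            key = (attr.kind, attr.category)
            if key in seen:
                raise DuplicateAttributeError(f"duplicate attribute {key}")
            seen.add(key)

    def _permitted(self, kind: AttributeKind) -> bool:
        return kind in _NODE_KINDS[self.node_role]

    def __repr__(self) -> str:  # keep role visible in error messages
        return f"MetadataNode({self.node_role.value}, name={self.name!r})"


@dataclass
class ProcessStep(_AttributeHolder):
    """An application of a named protocol linking two nodes (a ``Protocol REF`` column).

    May carry parameter values, an ISO-8601 date, a performer, and comments.
    Dates are stored and emitted as text; only the shape is the caller's
    responsibility, matching how the format itself treats them.
    """

    protocol_name: str
    attributes: list[AttributeValue] = field(default_factory=list)
    date: Optional[str] = None
    performer: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protocol_name:
            raise InvalidArgumentError("protocol name must be non-empty")
        seen: set[tuple[AttributeKind, str]] = set()
        for attr in self.attributes:
            if not self._permitted(attr.kind):
                raise RoleError(
                    f"attribute kind {attr.kind.value!r} is not permitted on a process step"
                )
            key = (attr.kind, attr.category)
            if key in seen:
                raise DuplicateAttributeError(f"duplicate attribute {key}")
            seen.add(key)

    def _permitted(self, kind: AttributeKind) -> bool:
        return kind in (AttributeKind.PARAMETER_VALUE, AttributeKind.COMMENT)

    @property
    def parameter_values(self) -> list[AttributeValue]:
        return [a for a in self.attributes if a.kind is AttributeKind.PARAMETER_VALUE]

    @property
    def comments(self) -> list[AttributeValue]:
        return [a for a in self.attributes if a.kind is AttributeKind.COMMENT]

    def __repr__(self) -> str:
        return f"ProcessStep({self.protocol_name!r})"


@dataclass(frozen=True)
class TableRow:
    """One complete path through the provenance graph: the unit of streaming.

    The chain strictly alternates node, process, node, ... and must start and
    end with a node, with at least node–process–node.
    """

    chain: tuple

    def __init__(self, chain: Iterable[Union[MetadataNode, ProcessStep]]):
        object.__setattr__(self, "chain", tuple(chain))
        self._validate()

    def _validate(self) -> None:
        chain = self.chain
        if len(chain) < 3:
            raise StructureError("a table row needs at least node-process-node")
        if len(chain) % 2 == 0:
            raise StructureError("a table row chain must have odd length (ends with a node)")
        for i, element in enumerate(chain):
            if i % 2 == 0 and not isinstance(element, MetadataNode):
                raise StructureError(f"chain position {i} must be a MetadataNode, got {element!r}")
            if i % 2 == 1 and not isinstance(element, ProcessStep):
                raise StructureError(f"chain position {i} must be a ProcessStep, got {element!r}")

    @property
    def nodes(self) -> tuple[MetadataNode, ...]:
        return self.chain[0::2]

    @property
    def processes(self) -> tuple[ProcessStep, ...]:
        return self.chain[1::2]


# --------------------------------------------------------------------------
# Investigation-level entities
# --------------------------------------------------------------------------

@dataclass
class Publication:
    pubmed_id: str = ""
    doi: str = ""
    author_list: str = ""
    title: str = ""
    status: Optional[OntologyAnnotation] = None


@dataclass
class Person:
    last_name: str = ""
    first_name: str = ""
    mid_initials: str = ""
    email: str = ""
    phone: str = ""
    fax: str = ""
    address: str = ""
    affiliation: str = ""
    roles: list[OntologyAnnotation] = field(default_factory=list)


@dataclass
class StudyFactor:
    name: str
    factor_type: Optional[OntologyAnnotation] = None


@dataclass
class ProtocolDefinition:
    """A protocol declared in the study's STUDY PROTOCOLS block."""

    name: str
    protocol_type: Optional[OntologyAnnotation] = None
    description: str = ""
    uri: str = ""
    version: str = ""
    parameters: list[OntologyAnnotation] = field(default_factory=list)
    components: list[tuple[str, Optional[OntologyAnnotation]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidArgumentError("protocol definition name must be non-empty")


@dataclass
class Assay:
    filename: str
    measurement_type: Optional[OntologyAnnotation] = None
    technology_type: Optional[OntologyAnnotation] = None
    technology_platform: str = ""

    def __post_init__(self) -> None:
        if not self.filename:
            raise InvalidArgumentError("assay filename must be non-empty")


@dataclass
class Study:
    identifier: str = ""
    filename: str = ""
    title: str = ""
    description: str = ""
    submission_date: Optional[str] = None
    public_release_date: Optional[str] = None
    design_descriptors: list[OntologyAnnotation] = field(default_factory=list)
    factors: list[StudyFactor] = field(default_factory=list)
    protocols: list[ProtocolDefinition] = field(default_factory=list)
    assays: list[Assay] = field(default_factory=list)
    publications: list[Publication] = field(default_factory=list)
    contacts: list[Person] = field(default_factory=list)


@dataclass
class Investigation:
    identifier: str = ""
    title: str = ""
    description: str = ""
    submission_date: Optional[str] = None
    public_release_date: Optional[str] = None
    ontology_sources: list[OntologySourceReference] = field(default_factory=list)
    publications: list[Publication] = field(default_factory=list)
    contacts: list[Person] = field(default_factory=list)
    studies: list[Study] = field(default_factory=list)


def _iter_annotations(inv: Investigation) -> Iterable[OntologyAnnotation]:
    for pub in inv.publications:
        if pub.status is not None:
            yield pub.status
    for person in inv.contacts:
        yield from person.roles
    for study in inv.studies:
        yield from study.design_descriptors
        for factor in study.factors:
            if factor.factor_type is not None:
                yield factor.factor_type
        for protocol in study.protocols:
            if protocol.protocol_type is not None:
                yield protocol.protocol_type
            yield from protocol.parameters
            for _, ctype in protocol.components:
                if ctype is not None:
                    yield ctype
        for assay in study.assays:
            if assay.measurement_type is not None:
                yield assay.measurement_type
            if assay.technology_type is not None:
                yield assay.technology_type
        for pub in study.publications:
            if pub.status is not None:
                yield pub.status
        for person in study.contacts:
            yield from person.roles


def validate_investigation(
    inv: Investigation,
    rows_by_study: Optional[Mapping[str, Iterable[TableRow]]] = None,
) -> list[str]:
    """Return a (possibly empty) list of human-readable issues.

    Checks: duplicate study filenames across the investigation, duplicate
    assay filenames within a study, duplicate ontology-source names,
    annotations referencing undeclared ontology sources, and — when
    ``rows_by_study`` maps study identifiers to their table rows — protocol
    references not declared in that study.  All findings are warnings here;
    only duplicate filenames are treated as fatal by the investigation
    serializer, since strict referential validation is the job of downstream
    validators.
    """
    issues: list[str] = []

    seen_sources: set[str] = set()
    for src in inv.ontology_sources:
        if src.name in seen_sources:
            issues.append(f"duplicate ontology source name {src.name!r}")
        seen_sources.add(src.name)

    seen_study_files: set[str] = set()
    for study in inv.studies:
        if study.filename:
            if study.filename in seen_study_files:
                issues.append(f"duplicate study filename {study.filename!r}")
            seen_study_files.add(study.filename)
        seen_assay_files: set[str] = set()
        for assay in study.assays:
            if assay.filename in seen_assay_files:
                issues.append(
                    f"duplicate assay filename {assay.filename!r} in study {study.identifier!r}"
                )
            seen_assay_files.add(assay.filename)

    declared = {src.name for src in inv.ontology_sources}
    reported: set[str] = set()
    for annotation in _iter_annotations(inv):
        if annotation.source_name and annotation.source_name not in declared:
            if annotation.source_name not in reported:
                issues.append(
                    f"annotation term source {annotation.source_name!r} is not a declared "
                    "ontology source"
                )
                reported.add(annotation.source_name)

    if rows_by_study:
        protocols_by_study = {
            study.identifier: {p.name for p in study.protocols} for study in inv.studies
        }
        for study_id, rows in rows_by_study.items():
            declared_protocols = protocols_by_study.get(study_id, set())
            missing: set[str] = set()
            for row in rows:
                for process in row.processes:
                    if process.protocol_name not in declared_protocols:
                        missing.add(process.protocol_name)
            for name in sorted(missing):
                issues.append(
                    f"protocol {name!r} used in rows of study {study_id!r} is not declared"
                )

    return issues
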