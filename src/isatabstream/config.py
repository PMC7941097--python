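"""YAML-driven serialization for the command line.

A config document describes the investigation-level metadata (identifier,
ontology sources, studies, protocols, assays) and, for each study and assay
table, where its rows come from: a delimited (tab-separated) input file plus
a *chain template* describing the node/process path each input row maps to.
Cell references in the template are written ``{Column Name}`` and are filled
from the corresponding input column; any other text is taken literally.

Example::

    investigation:
      identifier: inv1
      title: Example
    ontology_sources:
      - {name: NCBITAXON, file: "", version: "", description: ""}
    studies:
      - identifier: study1
        filename: s_study1.txt
        protocols:
          - {name: sample collection}
        rows:
          file: study_rows.tsv
          chain:
            - node: source
              name: "{Source}"
            - process: sample collection
            - node: sample
              name: "{Sample}"
              characteristics:
                - {category: Organism, value: "{Organism}",
                   accession: "{Taxon}", term_source: NCBITAXON}
        assays:
          - filename: a_assay1.txt
            rows:
              file: assay_rows.tsv
              chain:
                - node: sample
                  name: "{Sample}"
                - process: data collection
                - node: raw_data_file
                  name: "{File}"

Rows are streamed: each input line becomes one table row, written and
dropped immediately.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterator, Mapping, Optional, Union

import yaml

from .errors import InvalidArgumentError
from .investigation import render_investigation
from .model import (
    Assay,
    AttributeKind,
    AttributeValue,
    Investigation,
    MetadataNode,
    NodeRole,
    OntologyAnnotation,
    OntologySourceReference,
    Person,
    ProcessStep,
    ProtocolDefinition,
    Publication,
    Study,
    StudyFactor,
    TableRow,
)
from .streaming import open_table

__all__ = ["load_config", "write_from_config"]

_REF = re.compile(r"\{([^{}]+)\}")


def _fill(template: str, row: Mapping[str, str]) -> str:
    def lookup(match: re.Match) -> str:
        key = match.group(1)
        if key not in row:
            raise InvalidArgumentError(
                f"template references column {key!r} not present in the input "
                f"(available: {sorted(row)})"
            )
        return row[key]

    return _REF.sub(lookup, template)


def _annotation(spec, row: Mapping[str, str]) -> Optional[OntologyAnnotation]:
    if spec is None:
        return None
    if isinstance(spec, str):
        return OntologyAnnotation(term=_fill(spec, row))
    return OntologyAnnotation(
        term=_fill(str(spec.get("term", "")), row),
        accession=_fill(str(spec.get("accession", "")), row),
        source_name=_fill(str(spec.get("term_source", "")), row),
    )


def _attribute(kind: AttributeKind, spec: Mapping, row: Mapping[str, str]) -> AttributeValue:
    value: Union[str, OntologyAnnotation]
    raw_value = str(spec.get("value", ""))
    if spec.get("accession") or spec.get("term_source"):
        value = OntologyAnnotation(
            term=_fill(raw_value, row),
            accession=_fill(str(spec.get("accession", "")), row),
            source_name=_fill(str(spec.get("term_source", "")), row),
        )
    else:
        value = _fill(raw_value, row)
    unit = spec.get("unit")
    unit_value: Optional[Union[str, OntologyAnnotation]] = None
    if unit is not None:
        if isinstance(unit, Mapping):
            unit_value = _annotation(unit, row)
        else:
            unit_value = _fill(str(unit), row)
    return AttributeValue(kind, str(spec["category"]), value, unit_value)


_ATTRIBUTE_KEYS = (
    ("characteristics", AttributeKind.CHARACTERISTIC),
    ("factor_values", AttributeKind.FACTOR_VALUE),
    ("parameter_values", AttributeKind.PARAMETER_VALUE),
    ("comments", AttributeKind.COMMENT),
)


def _chain_element(spec, row: Mapping[str, str]):
    if "node" in spec:
        attributes = [
            _attribute(kind, attr_spec, row)
            for key, kind in _ATTRIBUTE_KEYS
            for attr_spec in spec.get(key, [])
        ]
        return MetadataNode(
            NodeRole(spec["node"]),
            _fill(str(spec.get("name", "")), row),
            attributes,
        )
    if "process" in spec or "protocol" in spec:
        if isinstance(spec, str):
            return ProcessStep(spec)
        name = spec.get("process") or spec.get("protocol")
        attributes = [
            _attribute(kind, attr_spec, row)
            for key, kind in (
                ("parameter_values", AttributeKind.PARAMETER_VALUE),
                ("comments", AttributeKind.COMMENT),
            )
            for attr_spec in spec.get(key, [])
        ]
        date = spec.get("date")
        performer = spec.get("performer")
        return ProcessStep(
            _fill(str(name), row),
            attributes,
            date=_fill(str(date), row) if date is not None else None,
            performer=_fill(str(performer), row) if performer is not None else None,
        )
    raise InvalidArgumentError(f"chain element must declare 'node' or 'process': {spec!r}")


def _iter_table_rows(rows_spec: Mapping, base_dir: Path) -> Iterator[TableRow]:
    chain_spec = rows_spec.get("chain")
    if not chain_spec:
        raise InvalidArgumentError("rows section needs a 'chain' template")
    source = rows_spec.get("file")
    if source is None:
        raise InvalidArgumentError("rows section needs a 'file' with delimited input")
    path = base_dir / source
    with open(path, newline="", encoding="utf-8") as handle:
        for record in csv.DictReader(handle, delimiter="\t"):
            yield TableRow([_chain_element(element, record) for element in chain_spec])


def _publication(spec: Mapping) -> Publication:
    return Publication(
        pubmed_id=str(spec.get("pubmed_id", "")),
        doi=str(spec.get("doi", "")),
        author_list=str(spec.get("author_list", "")),
        title=str(spec.get("title", "")),
        status=_annotation(spec.get("status"), {}),
    )


def _person(spec: Mapping) -> Person:
    return Person(
        last_name=str(spec.get("last_name", "")),
        first_name=str(spec.get("first_name", "")),
        mid_initials=str(spec.get("mid_initials", "")),
        email=str(spec.get("email", "")),
        phone=str(spec.get("phone", "")),
        fax=str(spec.get("fax", "")),
        address=str(spec.get("address", "")),
        affiliation=str(spec.get("affiliation", "")),
        roles=[_annotation(r, {}) for r in spec.get("roles", [])],
    )


def load_config(path: Union[str, Path]) -> tuple[Investigation, dict]:
    """Parse a config file into an :class:`Investigation` plus raw row specs.

    Returns the investigation object and a mapping
    ``{table filename: rows spec}`` for the study/assay tables whose rows are
    to be streamed from delimited inputs.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle) or {}

    inv_spec = doc.get("investigation", {}) or {}
    inv = Investigation(
        identifier=str(inv_spec.get("identifier", "")),
        title=str(inv_spec.get("title", "")),
        description=str(inv_spec.get("description", "")),
        submission_date=inv_spec.get("submission_date"),
        public_release_date=inv_spec.get("public_release_date"),
        ontology_sources=[
            OntologySourceReference(
                name=str(s["name"]),
                file=str(s.get("file", "")),
                version=str(s.get("version", "")),
                description=str(s.get("description", "")),
            )
            for s in doc.get("ontology_sources", [])
        ],
        publications=[_publication(p) for p in inv_spec.get("publications", [])],
        contacts=[_person(p) for p in inv_spec.get("contacts", [])],
    )

    row_sources: dict[str, Mapping] = {}
    for study_spec in doc.get("studies", []):
        study = Study(
            identifier=str(study_spec.get("identifier", "")),
            filename=str(study_spec.get("filename", "")),
            title=str(study_spec.get("title", "")),
            description=str(study_spec.get("description", "")),
            submission_date=study_spec.get("submission_date"),
            public_release_date=study_spec.get("public_release_date"),
            design_descriptors=[
                _annotation(d, {}) for d in study_spec.get("design_descriptors", [])
            ],
            factors=[
                StudyFactor(name=str(f["name"]), factor_type=_annotation(f.get("type"), {}))
                for f in study_spec.get("factors", [])
            ],
            protocols=[
                ProtocolDefinition(
                    name=str(p["name"]),
                    protocol_type=_annotation(p.get("type"), {}),
                    description=str(p.get("description", "")),
                    uri=str(p.get("uri", "")),
                    version=str(p.get("version", "")),
                    parameters=[_annotation(q, {}) for q in p.get("parameters", [])],
                )
                for p in study_spec.get("protocols", [])
            ],
            publications=[_publication(p) for p in study_spec.get("publications", [])],
            contacts=[_person(p) for p in study_spec.get("contacts", [])],
        )
        if "rows" in study_spec:
            row_sources[study.filename] = study_spec["rows"]
        for assay_spec in study_spec.get("assays", []):
            assay = Assay(
                filename=str(assay_spec["filename"]),
                measurement_type=_annotation(assay_spec.get("measurement_type"), {}),
                technology_type=_annotation(assay_spec.get("technology_type"), {}),
                technology_platform=str(assay_spec.get("technology_platform", "")),
            )
            study.assays.append(assay)
            if "rows" in assay_spec:
                row_sources[assay.filename] = assay_spec["rows"]
        inv.studies.append(study)

    return inv, row_sources


def write_from_config(config_path: Union[str, Path], out_dir: Union[str, Path]) -> dict[str, int]:
    """Render the investigation and all study/assay tables described by a config.

    Row inputs are resolved relative to the config file's directory.  Returns
    ``{filename: rows written}`` (the investigation file reports its line
    count).
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inv, row_sources = load_config(config_path)

    written: dict[str, int] = {}
    inv_name = f"i_{inv.identifier or 'investigation'}.txt"
    stats = render_investigation(inv, out_dir / inv_name)
    written[inv_name] = stats.rows_written

    for filename, rows_spec in row_sources.items():
        stream = open_table(out_dir / filename)
        for table_row in _iter_table_rows(rows_spec, config_path.parent):
            stream.write_row(table_row)
        written[filename] = stream.finish().rows_written
    return written
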