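"""Investigation file (``i_*.txt``) rendering.

The investigation file is laid out vertically: labelled sections (blocks)
each hold one field label per row and one column per entity — one column per
ontology source, per publication, per contact, and so on.  Ontology-annotated
fields expand into a value row, a ``Term Accession Number`` row and a
``Term Source REF`` row.  Unlike study and assay tables the investigation
file is small, so it is rendered whole rather than streamed.

Empty blocks are emitted with their label and label-only field rows rather
than omitted, which maximises compatibility with downstream parsers.
Multi-value cells (e.g. a protocol's parameter names) are packed with ``;``
and no surrounding spaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .errors import StructureError, ValidationError
from .model import (
    Investigation,
    OntologyAnnotation,
    Person,
    Publication,
    Study,
    validate_investigation,
)
from .streaming import WriteStats, escape_field, resolve_sink

__all__ = ["Block", "render_block", "render_investigation", "investigation_blocks"]

LINE_ENDING = "\n"


@dataclass(frozen=True)
class Block:
    """One labelled section: ordered (field label, cells) rows, one cell per entity."""

    label: str
    rows: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        widths = {len(cells) for _, cells in self.rows}
        if len(widths) > 1:
            raise StructureError(
                f"ragged block {self.label!r}: row widths {sorted(widths)}"
            )


def render_block(block: Block) -> list[str]:
    """Render a block as text lines: label line, then one line per field row.

    With zero entities the field rows are label-only (no trailing tab).
    """
    lines = [block.label + LINE_ENDING]
    for field_label, cells in block.rows:
        if cells:
            joined = "\t".join(escape_field(cell) for cell in cells)
            lines.append(f"{field_label}\t{joined}{LINE_ENDING}")
        else:
            lines.append(field_label + LINE_ENDING)
    return lines


# --------------------------------------------------------------------------
# Block construction from the model
# --------------------------------------------------------------------------

def _annotated(values: Sequence[Optional[OntologyAnnotation]]) -> tuple[tuple[str, ...], ...]:
    """Split annotations into (term, accession, source) cell tuples."""
    terms = tuple(v.term if v else "" for v in values)
    accessions = tuple(v.accession if v else "" for v in values)
    sources = tuple(v.source_name if v else "" for v in values)
    return terms, accessions, sources


def _joined(values: Sequence[Sequence[str]]) -> tuple[str, ...]:
    return tuple(";".join(v) for v in values)


def _ontology_source_block(inv: Investigation) -> Block:
    sources = inv.ontology_sources
    return Block(
        "ONTOLOGY SOURCE REFERENCE",
        (
            ("Term Source Name", tuple(s.name for s in sources)),
            ("Term Source File", tuple(s.file for s in sources)),
            ("Term Source Version", tuple(s.version for s in sources)),
            ("Term Source Description", tuple(s.description for s in sources)),
        ),
    )


def _investigation_block(inv: Investigation) -> Block:
    cell = lambda v: (v or "",)
    return Block(
        "INVESTIGATION",
        (
            ("Investigation Identifier", cell(inv.identifier)),
            ("Investigation Title", cell(inv.title)),
            ("Investigation Description", cell(inv.description)),
            ("Investigation Submission Date", cell(inv.submission_date)),
            ("Investigation Public Release Date", cell(inv.public_release_date)),
        ),
    )


def _publications_block(label_prefix: str, section: str, pubs: Sequence[Publication]) -> Block:
    status, status_tan, status_tsr = _annotated([p.status for p in pubs])
    return Block(
        section,
        (
            (f"{label_prefix} PubMed ID", tuple(p.pubmed_id for p in pubs)),
            (f"{label_prefix} Publication DOI", tuple(p.doi for p in pubs)),
            (f"{label_prefix} Publication Author List", tuple(p.author_list for p in pubs)),
            (f"{label_prefix} Publication Title", tuple(p.title for p in pubs)),
            (f"{label_prefix} Publication Status", status),
            (f"{label_prefix} Publication Status Term Accession Number", status_tan),
            (f"{label_prefix} Publication Status Term Source REF", status_tsr),
        ),
    )


def _contacts_block(label_prefix: str, section: str, people: Sequence[Person]) -> Block:
    roles = _joined([[r.term for r in p.roles] for p in people])
    roles_tan = _joined([[r.accession for r in p.roles] for p in people])
    roles_tsr = _joined([[r.source_name for r in p.roles] for p in people])
    return Block(
        section,
        (
            (f"{label_prefix} Person Last Name", tuple(p.last_name for p in people)),
            (f"{label_prefix} Person First Name", tuple(p.first_name for p in people)),
            (f"{label_prefix} Person Mid Initials", tuple(p.mid_initials for p in people)),
            (f"{label_prefix} Person Email", tuple(p.email for p in people)),
            (f"{label_prefix} Person Phone", tuple(p.phone for p in people)),
            (f"{label_prefix} Person Fax", tuple(p.fax for p in people)),
            (f"{label_prefix} Person Address", tuple(p.address for p in people)),
            (f"{label_prefix} Person Affiliation", tuple(p.affiliation for p in people)),
            (f"{label_prefix} Person Roles", roles),
            (f"{label_prefix} Person Roles Term Accession Number", roles_tan),
            (f"{label_prefix} Person Roles Term Source REF", roles_tsr),
        ),
    )


def _study_block(study: Study) -> Block:
    cell = lambda v: (v or "",)
    return Block(
        "STUDY",
        (
            ("Study Identifier", cell(study.identifier)),
            ("Study Title", cell(study.title)),
            ("Study Description", cell(study.description)),
            ("Study Submission Date", cell(study.submission_date)),
            ("Study Public Release Date", cell(study.public_release_date)),
            ("Study File Name", cell(study.filename)),
        ),
    )


def _design_block(study: Study) -> Block:
    types, tan, tsr = _annotated(study.design_descriptors)
    return Block(
        "STUDY DESIGN DESCRIPTORS",
        (
            ("Study Design Type", types),
            ("Study Design Type Term Accession Number", tan),
            ("Study Design Type Term Source REF", tsr),
        ),
    )


def _factors_block(study: Study) -> Block:
    types, tan, tsr = _annotated([f.factor_type for f in study.factors])
    return Block(
        "STUDY FACTORS",
        (
            ("Study Factor Name", tuple(f.name for f in study.factors)),
            ("Study Factor Type", types),
            ("Study Factor Type Term Accession Number", tan),
            ("Study Factor Type Term Source REF", tsr),
        ),
    )


def _assays_block(study: Study) -> Block:
    assays = study.assays
    mt, mt_tan, mt_tsr = _annotated([a.measurement_type for a in assays])
    tt, tt_tan, tt_tsr = _annotated([a.technology_type for a in assays])
    return Block(
        "STUDY ASSAYS",
        (
            ("Study Assay Measurement Type", mt),
            ("Study Assay Measurement Type Term Accession Number", mt_tan),
            ("Study Assay Measurement Type Term Source REF", mt_tsr),
            ("Study Assay Technology Type", tt),
            ("Study Assay Technology Type Term Accession Number", tt_tan),
            ("Study Assay Technology Type Term Source REF", tt_tsr),
            ("Study Assay Technology Platform", tuple(a.technology_platform for a in assays)),
            ("Study Assay File Name", tuple(a.filename for a in assays)),
        ),
    )


def _protocols_block(study: Study) -> Block:
    protos = study.protocols
    types, tan, tsr = _annotated([p.protocol_type for p in protos])
    params = _joined([[q.term for q in p.parameters] for p in protos])
    params_tan = _joined([[q.accession for q in p.parameters] for p in protos])
    params_tsr = _joined([[q.source_name for q in p.parameters] for p in protos])
    comp_names = _joined([[name for name, _ in p.components] for p in protos])
    comp_types = _joined(
        [[(ctype.term if ctype else "") for _, ctype in p.components] for p in protos]
    )
    comp_tan = _joined(
        [[(ctype.accession if ctype else "") for _, ctype in p.components] for p in protos]
    )
    comp_tsr = _joined(
        [[(ctype.source_name if ctype else "") for _, ctype in p.components] for p in protos]
    )
    return Block(
        "STUDY PROTOCOLS",
        (
            ("Study Protocol Name", tuple(p.name for p in protos)),
            ("Study Protocol Type", types),
            ("Study Protocol Type Term Accession Number", tan),
            ("Study Protocol Type Term Source REF", tsr),
            ("Study Protocol Description", tuple(p.description for p in protos)),
            ("Study Protocol URI", tuple(p.uri for p in protos)),
            ("Study Protocol Version", tuple(p.version for p in protos)),
            ("Study Protocol Parameters Name", params),
            ("Study Protocol Parameters Name Term Accession Number", params_tan),
            ("Study Protocol Parameters Name Term Source REF", params_tsr),
            ("Study Protocol Components Name", comp_names),
            ("Study Protocol Components Type", comp_types),
            ("Study Protocol Components Type Term Accession Number", comp_tan),
            ("Study Protocol Components Type Term Source REF", comp_tsr),
        ),
    )


def investigation_blocks(inv: Investigation) -> list[Block]:
    """Assemble all blocks in specification order (studies in insertion order)."""
    blocks = [
        _ontology_source_block(inv),
        _investigation_block(inv),
        _publications_block("Investigation", "INVESTIGATION PUBLICATIONS", inv.publications),
        _contacts_block("Investigation", "INVESTIGATION CONTACTS", inv.contacts),
    ]
    for study in inv.studies:
        blocks.extend(
            [
                _study_block(study),
                _design_block(study),
                _publications_block("Study", "STUDY PUBLICATIONS", study.publications),
                _factors_block(study),
                _assays_block(study),
                _protocols_block(study),
                _contacts_block("Study", "STUDY CONTACTS", study.contacts),
            ]
        )
    return blocks


def render_investigation(inv: Investigation, sink: Union[str, object]) -> WriteStats:
    """Render the full investigation file to a path or writable text sink.

    Duplicate study or assay filenames are fatal; all other findings of
    :func:`isatabstream.model.validate_investigation` are warnings left to
    downstream validators.
    """
    fatal = [
        issue
        for issue in validate_investigation(inv)
        if issue.startswith("duplicate study filename")
        or issue.startswith("duplicate assay filename")
    ]
    if fatal:
        raise ValidationError("; ".join(fatal))
    handle, owns = resolve_sink(sink)
    lines_written = 0
    bytes_written = 0
    try:
        for block in investigation_blocks(inv):
            for line in render_block(block):
                handle.write(line)
                lines_written += 1
                bytes_written += len(line.encode("utf-8"))
        flush = getattr(handle, "flush", None)
        if flush is not None:
            flush()
    finally:
        if owns:
            handle.close()
    return WriteStats(rows_written=lines_written, bytes_written=bytes_written)
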