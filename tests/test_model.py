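"""Object-model invariants: annotations, attributes, chains, investigation checks."""

import pytest

from isatabstream import (
    Assay,
    AttributeKind,
    AttributeValue,
    DuplicateAttributeError,
    Investigation,
    InvalidArgumentError,
    MetadataNode,
    NodeRole,
    OntologyAnnotation,
    OntologySourceReference,
    ProcessStep,
    RoleError,
    StructureError,
    Study,
    StudyFactor,
    TableRow,
    make_ontology_annotation,
    validate_investigation,
)


class TestOntologyAnnotation:
    def test_constructor_keeps_fields_verbatim(self):
        ann = make_ontology_annotation(
            "leaf", "http://purl.obolibrary.org/obo/PO_0025034", "PO"
        )
        assert (ann.term, ann.accession, ann.source_name) == (
            "leaf",
            "http://purl.obolibrary.org/obo/PO_0025034",
            "PO",
        )

    def test_empty_accession_and_source_are_allowed(self):
        ann = make_ontology_annotation("plant")
        assert ann.accession == "" and ann.source_name == ""

    def test_empty_term_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_ontology_annotation("", "X", "Y")


class TestAttributeValue:
    @pytest.mark.parametrize("category", ["", "a\tb", "a[b]", "a\nb"])
    def test_bad_categories_rejected(self, category):
        with pytest.raises(InvalidArgumentError):
            AttributeValue(AttributeKind.CHARACTERISTIC, category, "v")

    def test_annotated_value_may_not_carry_unit(self):
        with pytest.raises(InvalidArgumentError):
            AttributeValue(
                AttributeKind.CHARACTERISTIC,
                "Height",
                OntologyAnnotation("tall"),
                unit="cm",
            )

    def test_plain_value_with_annotated_unit_is_fine(self):
        attr = AttributeValue(
            AttributeKind.CHARACTERISTIC,
            "Height",
            "12",
            unit=OntologyAnnotation("centimeter", "obo:UO_0000015", "UO"),
        )
        assert attr.unit.term == "centimeter"


class TestAttributeRules:
    def test_add_characteristic_preserves_order(self):
        sample = MetadataNode(NodeRole.SAMPLE, "sm")
        sample.add_attribute(
            AttributeValue(AttributeKind.CHARACTERISTIC, "Organism", "Hordeum vulgare")
        )
        sample.add_attribute(AttributeValue(AttributeKind.CHARACTERISTIC, "Age", "7"))
        assert [a.category for a in sample.attributes] == ["Organism", "Age"]

    def test_duplicate_kind_category_rejected(self):
        sample = MetadataNode(NodeRole.SAMPLE, "sm")
        sample.add_attribute(AttributeValue(AttributeKind.CHARACTERISTIC, "Organism", "x"))
        with pytest.raises(DuplicateAttributeError):
            sample.add_attribute(
                AttributeValue(AttributeKind.CHARACTERISTIC, "Organism", "y")
            )

    def test_same_category_different_kind_is_allowed(self):
        sample = MetadataNode(NodeRole.SAMPLE, "sm")
        sample.add_attribute(AttributeValue(AttributeKind.CHARACTERISTIC, "Site", "x"))
        sample.add_attribute(AttributeValue(AttributeKind.COMMENT, "Site", "y"))
        assert len(sample.attributes) == 2

    def test_factor_value_on_source_is_a_role_error(self):
        source = MetadataNode(NodeRole.SOURCE, "s")
        with pytest.raises(RoleError):
            source.add_attribute(
                AttributeValue(AttributeKind.FACTOR_VALUE, "Treatment", "drought")
            )

    def test_parameter_value_only_on_processes(self):
        with pytest.raises(RoleError):
            MetadataNode(NodeRole.SAMPLE, "sm").add_attribute(
                AttributeValue(AttributeKind.PARAMETER_VALUE, "Rate", "1")
            )
        proc = ProcessStep("watering")
        proc.add_attribute(AttributeValue(AttributeKind.PARAMETER_VALUE, "Rate", "1"))
        assert proc.parameter_values[0].category == "Rate"

    def test_empty_protocol_name_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ProcessStep("")


class TestTableRow:
    def test_minimal_chain_accepted(self, minimal_row):
        assert len(minimal_row.chain) == 3
        assert [n.name for n in minimal_row.nodes] == ["s1", "sm1"]

    @pytest.mark.parametrize(
        "chain",
        [
            [],
            [MetadataNode(NodeRole.SOURCE, "s")],
            [MetadataNode(NodeRole.SOURCE, "s"), ProcessStep("p")],
            [
                MetadataNode(NodeRole.SOURCE, "s"),
                MetadataNode(NodeRole.SAMPLE, "m"),
                MetadataNode(NodeRole.SAMPLE, "m2"),
            ],
            [ProcessStep("p"), MetadataNode(NodeRole.SAMPLE, "m"), ProcessStep("q")],
        ],
    )
    def test_malformed_chains_rejected(self, chain):
        with pytest.raises(StructureError):
            TableRow(chain)


class TestValidateInvestigation:
    def test_well_formed_minimal_investigation_is_clean(self):
        inv = Investigation(
            identifier="i1",
            studies=[Study(identifier="s1", filename="s_x.txt", assays=[Assay("a_x.txt")])],
        )
        assert validate_investigation(inv) == []

    def test_duplicate_study_filenames_reported(self):
        inv = Investigation(
            studies=[
                Study(identifier="s1", filename="s_x.txt"),
                Study(identifier="s2", filename="s_x.txt"),
            ]
        )
        issues = validate_investigation(inv)
        assert len(issues) == 1 and "s_x.txt" in issues[0]

    def test_undeclared_ontology_source_named_in_issue(self):
        inv = Investigation(
            studies=[
                Study(
                    identifier="s1",
                    filename="s_x.txt",
                    design_descriptors=[OntologyAnnotation("growth study", "acc", "PO")],
                )
            ]
        )
        issues = validate_investigation(inv)
        assert len(issues) == 1 and "'PO'" in issues[0]

    def test_declared_source_produces_no_issue(self):
        inv = Investigation(
            ontology_sources=[OntologySourceReference("PO")],
            studies=[
                Study(
                    identifier="s1",
                    filename="s_x.txt",
                    factors=[StudyFactor("drought", OntologyAnnotation("stress", "", "PO"))],
                )
            ],
        )
        assert validate_investigation(inv) == []

    def test_undeclared_protocol_reference_in_rows(self, minimal_row):
        inv = Investigation(studies=[Study(identifier="s1", filename="s_x.txt")])
        issues = validate_investigation(inv, rows_by_study={"s1": [minimal_row]})
        assert any("sampling" in issue for issue in issues)
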