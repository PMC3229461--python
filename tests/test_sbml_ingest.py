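"""SBML Level 2 parsing: record extraction, id preservation, units, math."""

import pytest
from lxml import etree

from sblink import (
    IntegrityError,
    ParseError,
    UnsupportedLevelError,
    ValidationError,
    normalize_unit_definitions,
    parse_sbml_document,
    resolve_function_references,
)
from sblink.records import (
    ArgumentKind,
    MathExpression,
    ReactionSpeciesRole,
    SbaseRecord,
)
from sblink.sbml import mathml_identifiers, seed_base_units

from conftest import TWO_SPECIES_DOC, wrap_model


def xml_walk_counts(doc: str) -> dict[str, int]:
    """Independent oracle: count SBML elements by a plain XML walk."""
    root = etree.fromstring(doc.encode())
    counts: dict[str, int] = {}
    for el in root.iter():
        if isinstance(el.tag, str):
            local = etree.QName(el).localname
            counts[local] = counts.get(local, 0) + 1
    return counts


class TestParseDocument:
    def test_counts_match_independent_xml_walk(self):
        bundle = parse_sbml_document(TWO_SPECIES_DOC, "ds")
        walk = xml_walk_counts(TWO_SPECIES_DOC)
        assert len(bundle.species) == walk["species"] == 2
        assert len(bundle.reactions) == walk["reaction"] == 1
        assert len(bundle.compartments) == walk["compartment"] == 1
        # 2 reactants + 1 product
        assert len(bundle.reaction_species) == walk["speciesReference"] == 3
        roles = [rs.role for rs in bundle.reaction_species]
        assert roles.count(ReactionSpeciesRole.REACTANT) == 2
        assert roles.count(ReactionSpeciesRole.PRODUCT) == 1

    def test_empty_species_list_yields_model_only(self):
        doc = wrap_model("<listOfSpecies/>")
        bundle = parse_sbml_document(doc, "ds")
        assert bundle.model.sbml_id == "M1"
        assert bundle.species == []

    def test_sbml_id_preserved_and_absent_name_stays_absent(self):
        doc = wrap_model("", 'id="Hynne2001_Glycolysis"')
        bundle = parse_sbml_document(doc, "ds")
        assert bundle.model.sbml_id == "Hynne2001_Glycolysis"
        assert bundle.model.name is None

    def test_every_sbml_id_appears_on_exactly_one_record(self):
        bundle = parse_sbml_document(TWO_SPECIES_DOC, "ds")
        ids = [
            r.sbml_id
            for r in bundle.all_sbase_records()
            if getattr(r, "sbml_id", None)
        ]
        assert sorted(ids) == sorted(set(ids))
        assert set(ids) >= {"M1", "A", "B", "R1", "cell"}

    def test_every_record_exposes_sbase_fields(self):
        bundle = parse_sbml_document(TWO_SPECIES_DOC, "ds")
        for rec in bundle.all_sbase_records():
            assert isinstance(rec, SbaseRecord)
            for field in ("id", "meta_id", "sbo_term", "notes", "annotation"):
                assert hasattr(rec, field)

    def test_malformed_xml_error_names_line(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_sbml_document("<sbml>\n<broken\n", "ds")

    def test_non_level2_rejected(self):
        doc = TWO_SPECIES_DOC.replace('level="2"', 'level="3"')
        with pytest.raises(UnsupportedLevelError):
            parse_sbml_document(doc, "ds")

    def test_duplicate_sbml_id_rejected(self):
        doc = wrap_model(
            "<listOfSpecies>"
            '<species id="X" compartment="c"/><species id="X" compartment="c"/>'
            "</listOfSpecies>"
            '<listOfCompartments><compartment id="c"/></listOfCompartments>'
        )
        with pytest.raises(IntegrityError, match="X"):
            parse_sbml_document(doc, "ds")

    def test_species_referencing_unknown_compartment_rejected(self):
        doc = wrap_model(
            '<listOfSpecies><species id="X" compartment="nowhere"/></listOfSpecies>'
        )
        with pytest.raises(IntegrityError, match="nowhere"):
            parse_sbml_document(doc, "ds")

    def test_sbml_defaults_applied(self):
        bundle = parse_sbml_document(TWO_SPECIES_DOC, "ds")
        rxn = bundle.reactions[0]
        assert rxn.reversible is True and rxn.fast is False
        a = next(s for s in bundle.species if s.sbml_id == "A")
        assert a.constant is False and a.boundary_condition is False
        assert a.initial_concentration == 2 and a.initial_amount is None

    def test_deterministic_ids_are_reproducible(self):
        b1 = parse_sbml_document(TWO_SPECIES_DOC, "ds", deterministic_ids=True)
        b2 = parse_sbml_document(TWO_SPECIES_DOC, "ds", deterministic_ids=True)
        assert b1.model.id == b2.model.id
        assert [s.id for s in b1.species] == [s.id for s in b2.species]

    def test_raw_annotation_subtree_stored_verbatim_enough_to_reparse(self):
        ann = (
            "<annotation><custom xmlns=\"urn:x\">payload</custom></annotation>"
        )
        doc = wrap_model(
            '<listOfCompartments><compartment id="c">'
            + ann
            + "</compartment></listOfCompartments>"
        )
        bundle = parse_sbml_document(doc, "ds")
        stored = bundle.compartments[0].annotation
        assert stored is not None
        assert etree.fromstring(stored.encode()) is not None
        assert "payload" in stored


class TestFunctionReferences:
    FUNCS_DOC = wrap_model(
        "<listOfFunctionDefinitions>"
        '<functionDefinition id="pow3"/>'
        '<functionDefinition id="f"/>'
        "</listOfFunctionDefinitions>"
        '<listOfCompartments><compartment id="c"/></listOfCompartments>'
        '<listOfSpecies><species id="S1" compartment="c"/></listOfSpecies>'
    )

    def _bundle(self):
        return parse_sbml_document(self.FUNCS_DOC, "ds")

    def test_function_reference_resolved_to_definition(self):
        bundle = self._bundle()
        expr = MathExpression(
            owner_id="kl1",
            mathml='<math><apply><ci>pow3</ci><cn>2</cn></apply></math>',
        )
        resolve_function_references(expr, bundle.function_definitions)
        assert len(expr.arguments) == 1
        arg = expr.arguments[0]
        assert arg.symbol == "pow3" and arg.kind == ArgumentKind.FUNCTION
        pow3 = next(
            f for f in bundle.function_definitions if f.sbml_id == "pow3"
        )
        assert arg.function_id == pow3.id

    def test_numeric_only_math_has_no_arguments(self):
        expr = MathExpression(
            owner_id="kl1", mathml="<math><cn>3.5</cn></math>"
        )
        resolve_function_references(expr, [])
        assert expr.arguments == []

    def test_species_and_function_classified_separately(self):
        bundle = self._bundle()
        expr = MathExpression(
            owner_id="kl1",
            mathml="<math><apply><ci>f</ci><ci>S1</ci></apply></math>",
        )
        resolve_function_references(
            expr,
            bundle.function_definitions,
            species={s.sbml_id: s.id for s in bundle.species},
        )
        kinds = {a.symbol: a.kind for a in expr.arguments}
        assert kinds == {
            "f": ArgumentKind.FUNCTION,
            "S1": ArgumentKind.SPECIES,
        }

    def test_unresolved_identifier_flagged_not_fatal(self):
        expr = MathExpression(
            owner_id="kl1", mathml="<math><ci>mystery</ci></math>"
        )
        resolve_function_references(expr, [])
        assert expr.arguments[0].kind == ArgumentKind.UNRESOLVED

    def test_mathml_identifier_extraction_handles_prefixes(self):
        assert mathml_identifiers(
            '<m:math xmlns:m="u"><m:ci> x </m:ci><m:ci>y</m:ci></m:math>'
        ) == ["x", "y"]


class TestUnits:
    UNITS_DOC = wrap_model(
        "<listOfUnitDefinitions>"
        '<unitDefinition id="mmol_per_l"><listOfUnits>'
        '<unit kind="mole" scale="-3"/>'
        '<unit kind="litre" exponent="-1"/>'
        "</listOfUnits></unitDefinition>"
        "</listOfUnitDefinitions>"
    )

    def test_user_unit_composed_of_base_units(self):
        bundle = parse_sbml_document(self.UNITS_DOC, "ds")
        base, user = normalize_unit_definitions(bundle)
        assert [u.sbml_id for u in user] == ["mmol_per_l"]
        assert user[0].model_id == bundle.model.id
        rows = [
            r for r in bundle.units if r.unit_definition_id == user[0].id
        ]
        assert len(rows) == 2
        assert {(r.base_unit_kind, r.scale, r.exponent) for r in rows} == {
            ("mole", -3, 1.0),
            ("litre", 0, -1.0),
        }

    def test_base_units_carry_no_model_id(self):
        base = seed_base_units()
        second = next(u for u in base if u.sbml_id == "second")
        assert second.model_id is None

    def test_user_unit_built_on_user_unit_rejected(self):
        doc = wrap_model(
            "<listOfUnitDefinitions>"
            '<unitDefinition id="mmol_per_l"><listOfUnits>'
            '<unit kind="mole" scale="-3"/></listOfUnits></unitDefinition>'
            '<unitDefinition id="derived"><listOfUnits>'
            '<unit kind="mmol_per_l"/></listOfUnits></unitDefinition>'
            "</listOfUnitDefinitions>"
        )
        bundle = parse_sbml_document(doc, "ds")
        with pytest.raises(ValidationError, match="mmol_per_l"):
            normalize_unit_definitions(bundle)


def test_corpus_roundtrip_counts_match_xml_walk(corpus):
    """Record counts per entity kind equal an independent element walk,
    for every generated document."""
    for text in corpus["docs"].values():
        bundle = parse_sbml_document(text, "ds")
        walk = xml_walk_counts(text)
        assert len(bundle.species) == walk.get("species", 0)
        assert len(bundle.reactions) == walk.get("reaction", 0)
        assert len(bundle.compartments) == walk.get("compartment", 0)
        assert len(bundle.kinetic_laws) == walk.get("kineticLaw", 0)
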