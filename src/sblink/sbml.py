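"""SBML Level 2 ingest.

Parses BioModels-style SBML Level 2 documents (versions 1-4) into the
package's entity records.  Only the entity kinds of the relational model are
materialized (model, compartments, species, reactions and participants,
kinetic laws, parameters, units, functions, rules, constraints, initial
assignments, events); any other construct survives verbatim inside the
stored document text.  The raw ``<annotation>`` subtree of every element is
kept untouched on its record so that annotation extraction can run later,
and MathML payloads are stored as whitespace-canonicalized text, never
evaluated.
"""

from __future__ import annotations

import re

from lxml import etree

from .errors import IntegrityError, ParseError, UnsupportedLevelError
from .records import (
    BASE_UNIT_KINDS,
    ArgumentKind,
    CompartmentRecord,
    CompartmentTypeRecord,
    ConstraintRecord,
    EventAssignmentRecord,
    EventDelayRecord,
    EventRecord,
    EventTriggerRecord,
    FunctionDefinitionRecord,
    IdFactory,
    InitialAssignmentRecord,
    KineticLawParameterRecord,
    KineticLawRecord,
    MathArgument,
    MathExpression,
    ModelBundle,
    ModelRecord,
    ParameterRecord,
    ReactionRecord,
    ReactionSpeciesRecord,
    ReactionSpeciesRole,
    RuleRecord,
    RuleType,
    SpeciesRecord,
    SpeciesTypeRecord,
    UnitDefinitionRecord,
    UnitRecord,
)

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _child(el: etree._Element, name: str) -> etree._Element | None:
    for c in el:
        if isinstance(c.tag, str) and _local(c) == name:
            return c
    return None


def _children(el: etree._Element, name: str) -> list[etree._Element]:
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def _bool(el: etree._Element, attr: str, default: bool) -> bool:
    v = el.get(attr)
    if v is None:
        return default
    return v in ("true", "1")


def _float(el: etree._Element, attr: str) -> float | None:
    v = el.get(attr)
    return None if v is None else float(v)


def _int(el: etree._Element, attr: str) -> int | None:
    v = el.get(attr)
    return None if v is None else int(v)


def canonicalize_mathml(text: str | None) -> str | None:
    """Whitespace-normalize a MathML fragment for stable text comparison."""
    if text is None:
        return None
    text = re.sub(r">\s+<", "><", text.strip())
    return re.sub(r"\s+", " ", text)


def _serialize(el: etree._Element | None) -> str | None:
    if el is None:
        return None
    return canonicalize_mathml(etree.tostring(el, encoding="unicode"))


def _text_content(el: etree._Element | None) -> str | None:
    if el is None:
        return None
    txt = " ".join(el.itertext()).strip()
    return re.sub(r"\s+", " ", txt) or None


class _SbaseReader:
    """Pulls the shared Sbase attributes off an SBML element."""

    @staticmethod
    def fields(el: etree._Element) -> dict:
        ann = _child(el, "annotation")
        notes = _child(el, "notes")
        return {
            "meta_id": el.get("metaid"),
            "sbo_term": el.get("sboTerm"),
            "notes": _text_content(notes),
            "annotation": None
            if ann is None
            else etree.tostring(ann, encoding="unicode"),
        }


def parse_sbml_document(
    document: str | bytes,
    data_source_id: str,
    *,
    deterministic_ids: bool = False,
) -> ModelBundle:
    """Parse one SBML Level 2 document into a :class:`ModelBundle`.

    Every SBML element of a modeled kind becomes exactly one record whose
    ``sbml_id`` equals the element's ``id`` attribute; internal ids are fresh
    opaque identifiers (derived deterministically from ``(data_source_id,
    kind, sbmlId)`` when *deterministic_ids* is set).

    Raises
    ------
    ParseError
        if the XML is malformed (the message names the offending line).
    UnsupportedLevelError
        if the document does not declare SBML Level 2.
    IntegrityError
        if two elements of the same model share an ``sbml_id``.
    """
    if isinstance(document, str):
        raw = document
        data = document.encode()
    else:
        data = document
        raw = document.decode("utf-8", errors="replace")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc

    if _local(root) != "sbml":
        raise ParseError(f"root element is <{_local(root)}>, expected <sbml>")
    level = _int(root, "level")
    if level != 2:
        raise UnsupportedLevelError(
            f"SBML level {level!r} not supported (only Level 2, versions 1-4)"
        )
    version = _int(root, "version") or 1
    model_el = _child(root, "model")
    if model_el is None:
        raise ParseError("document has no <model> element")

    # id scope includes the model's own sbmlId: two models of one data
    # source may reuse element ids ("cytoplasm") without colliding
    ids = IdFactory(
        f"{data_source_id}/{model_el.get('id') or ''}",
        deterministic=deterministic_ids,
    )
    seen_sbml_ids: set[str] = set()

    def fresh(kind: str, sbml_id: str | None, ordinal: int | None = None) -> str:
        key = sbml_id if sbml_id is not None else f"{kind}-{ordinal}"
        return ids.new_id(kind, key)

    def register(sbml_id: str | None) -> None:
        if sbml_id is None:
            return
        if sbml_id in seen_sbml_ids:
            raise IntegrityError(f"duplicate sbmlId {sbml_id!r} within model")
        seen_sbml_ids.add(sbml_id)

    m_sbml_id = model_el.get("id") or ""
    register(m_sbml_id or None)
    model = ModelRecord(
        id=fresh("model", m_sbml_id),
        sbml_id=m_sbml_id,
        name=model_el.get("name"),
        sbml_level=level,
        sbml_version=version,
        data_source_id=data_source_id,
        sbml_file=raw,
        **_SbaseReader.fields(model_el),
    )
    bundle = ModelBundle(model=model)

    # --- units -----------------------------------------------------------
    lo = _child(model_el, "listOfUnitDefinitions")
    if lo is not None:
        for ud in _children(lo, "unitDefinition"):
            sid = ud.get("id")
            register(sid)
            rec = UnitDefinitionRecord(
                id=fresh("unitDefinition", sid),
                sbml_id=sid or "",
                name=ud.get("name"),
                model_id=model.id,
                **_SbaseReader.fields(ud),
            )
            bundle.unit_definitions.append(rec)
            lu = _child(ud, "listOfUnits")
            for u in [] if lu is None else _children(lu, "unit"):
                bundle.units.append(
                    UnitRecord(
                        unit_definition_id=rec.id,
                        base_unit_kind=u.get("kind", ""),
                        exponent=_float(u, "exponent") or 1.0,
                        scale=_int(u, "scale") or 0,
                        multiplier=_float(u, "multiplier") or 1.0,
                    )
                )

    # --- compartment/species types --------------------------------------
    lo = _child(model_el, "listOfCompartmentTypes")
    if lo is not None:
        for el in _children(lo, "compartmentType"):
            sid = el.get("id")
            register(sid)
            bundle.compartment_types.append(
                CompartmentTypeRecord(
                    id=fresh("compartmentType", sid),
                    model_id=model.id,
                    sbml_id=sid or "",
                    name=el.get("name"),
                    **_SbaseReader.fields(el),
                )
            )
    lo = _child(model_el, "listOfSpeciesTypes")
    if lo is not None:
        for el in _children(lo, "speciesType"):
            sid = el.get("id")
            register(sid)
            bundle.species_types.append(
                SpeciesTypeRecord(
                    id=fresh("speciesType", sid),
                    model_id=model.id,
                    sbml_id=sid or "",
                    name=el.get("name"),
                    **_SbaseReader.fields(el),
                )
            )

    # --- compartments ----------------------------------------------------
    comp_by_sbml: dict[str, str] = {}
    type_by_sbml = {t.sbml_id: t.id for t in bundle.compartment_types}
    sptype_by_sbml = {t.sbml_id: t.id for t in bundle.species_types}
    unit_by_sbml = {u.sbml_id: u.id for u in bundle.unit_definitions}
    lo = _child(model_el, "listOfCompartments")
    if lo is not None:
        for el in _children(lo, "compartment"):
            sid = el.get("id")
            register(sid)
            rec = CompartmentRecord(
                id=fresh("compartment", sid),
                model_id=model.id,
                sbml_id=sid or "",
                name=el.get("name"),
                compartment_type_id=type_by_sbml.get(el.get("compartmentType", "")),
                spatial_dimensions=_int(el, "spatialDimensions"),
                size=_float(el, "size"),
                units_id=unit_by_sbml.get(el.get("units", "")),
                outside=el.get("outside"),
                constant=_bool(el, "constant", True),
                **_SbaseReader.fields(el),
            )
            bundle.compartments.append(rec)
            comp_by_sbml[rec.sbml_id] = rec.id

    # --- species ---------------------------------------------------------
    species_by_sbml: dict[str, str] = {}
    lo = _child(model_el, "listOfSpecies")
    if lo is not None:
        for el in _children(lo, "species"):
            sid = el.get("id")
            register(sid)
            compartment = el.get("compartment", "")
            if compartment and compartment not in comp_by_sbml:
                raise IntegrityError(
                    f"species {sid!r} references unknown compartment {compartment!r}"
                )
            rec = SpeciesRecord(
                id=fresh("species", sid),
                model_id=model.id,
                sbml_id=sid or "",
                name=el.get("name"),
                species_type_id=sptype_by_sbml.get(el.get("speciesType", "")),
                compartment_id=comp_by_sbml.get(compartment),
                initial_amount=_float(el, "initialAmount"),
                initial_concentration=_float(el, "initialConcentration"),
                substance_units_id=unit_by_sbml.get(el.get("substanceUnits", "")),
                has_only_substance_units=_bool(el, "hasOnlySubstanceUnits", False),
                boundary_condition=_bool(el, "boundaryCondition", False),
                charge=_int(el, "charge"),
                constant=_bool(el, "constant", False),
                **_SbaseReader.fields(el),
            )
            bundle.species.append(rec)
            species_by_sbml[rec.sbml_id] = rec.id

    # --- global parameters ----------------------------------------------
    lo = _child(model_el, "listOfParameters")
    if lo is not None:
        for el in _children(lo, "parameter"):
            sid = el.get("id")
            register(sid)
            bundle.parameters.append(
                ParameterRecord(
                    id=fresh("parameter", sid),
                    model_id=model.id,
                    sbml_id=sid or "",
                    name=el.get("name"),
                    value=_float(el, "value"),
                    units_id=unit_by_sbml.get(el.get("units", "")),
                    constant=_bool(el, "constant", True),
                    **_SbaseReader.fields(el),
                )
            )

    # --- function definitions -------------------------------------------
    lo = _child(model_el, "listOfFunctionDefinitions")
    if lo is not None:
        for el in _children(lo, "functionDefinition"):
            sid = el.get("id")
            register(sid)
            bundle.function_definitions.append(
                FunctionDefinitionRecord(
                    id=fresh("functionDefinition", sid),
                    model_id=model.id,
                    sbml_id=sid or "",
                    name=el.get("name"),
                    mathml=_serialize(_child(el, "math")),
                    **_SbaseReader.fields(el),
                )
            )

    # --- rules / constraints / initial assignments ----------------------
    lo = _child(model_el, "listOfRules")
    if lo is not None:
        kinds = {
            "algebraicRule": RuleType.ALGEBRAIC,
            "assignmentRule": RuleType.ASSIGNMENT,
            "rateRule": RuleType.RATE,
        }
        for i, el in enumerate(c for c in lo if isinstance(c.tag, str)):
            kind = kinds.get(_local(el))
            if kind is None:
                continue
            bundle.rules.append(
                RuleRecord(
                    id=fresh("rule", None, i),
                    model_id=model.id,
                    rule_type=kind,
                    variable=el.get("variable"),
                    mathml=_serialize(_child(el, "math")),
                    **_SbaseReader.fields(el),
                )
            )
    lo = _child(model_el, "listOfConstraints")
    if lo is not None:
        for i, el in enumerate(_children(lo, "constraint")):
            bundle.constraints.append(
                ConstraintRecord(
                    id=fresh("constraint", None, i),
                    model_id=model.id,
                    mathml=_serialize(_child(el, "math")),
                    message=_text_content(_child(el, "message")),
                    **_SbaseReader.fields(el),
                )
            )
    lo = _child(model_el, "listOfInitialAssignments")
    if lo is not None:
        for i, el in enumerate(_children(lo, "initialAssignment")):
            bundle.initial_assignments.append(
                InitialAssignmentRecord(
                    id=fresh("initialAssignment", None, i),
                    model_id=model.id,
                    symbol=el.get("symbol", ""),
                    mathml=_serialize(_child(el, "math")),
                    **_SbaseReader.fields(el),
                )
            )

    # --- reactions -------------------------------------------------------
    lo = _child(model_el, "listOfReactions")
    if lo is not None:
        for el in _children(lo, "reaction"):
            sid = el.get("id")
            register(sid)
            rxn = ReactionRecord(
                id=fresh("reaction", sid),
                model_id=model.id,
                sbml_id=sid or "",
                name=el.get("name"),
                reversible=_bool(el, "reversible", True),
                fast=_bool(el, "fast", False),
                **_SbaseReader.fields(el),
            )
            bundle.reactions.append(rxn)
            for list_name, role in (
                ("listOfReactants", ReactionSpeciesRole.REACTANT),
                ("listOfProducts", ReactionSpeciesRole.PRODUCT),
                ("listOfModifiers", ReactionSpeciesRole.MODIFIER),
            ):
                plist = _child(el, list_name)
                if plist is None:
                    continue
                tag = (
                    "modifierSpeciesReference"
                    if role is ReactionSpeciesRole.MODIFIER
                    else "speciesReference"
                )
                for j, ref in enumerate(_children(plist, tag)):
                    sp = ref.get("species", "")
                    if sp and sp not in species_by_sbml:
                        raise IntegrityError(
                            f"reaction {sid!r} references unknown species {sp!r}"
                        )
                    smath = _serialize(_child(ref, "stoichiometryMath"))
                    stoich = _float(ref, "stoichiometry")
                    if (
                        role is not ReactionSpeciesRole.MODIFIER
                        and stoich is None
                        and smath is None
                    ):
                        stoich = 1.0  # SBML default stoichiometry
                    bundle.reaction_species.append(
                        ReactionSpeciesRecord(
                            id=fresh(
                                "reactionSpecies", f"{sid}/{role.value}/{sp}/{j}"
                            ),
                            reaction_id=rxn.id,
                            species_id=species_by_sbml.get(sp, sp),
                            role=role,
                            stoichiometry=None
                            if role is ReactionSpeciesRole.MODIFIER
                            else stoich,
                            stoichiometry_math=smath,
                            sbml_id=ref.get("id"),
                            name=ref.get("name"),
                            **_SbaseReader.fields(ref),
                        )
                    )
            kl = _child(el, "kineticLaw")
            if kl is not None:
                klrec = KineticLawRecord(
                    id=fresh("kineticLaw", f"{sid}/kl"),
                    reaction_id=rxn.id,
                    mathml=_serialize(_child(kl, "math")),
                    **_SbaseReader.fields(kl),
                )
                rxn.kinetic_law_id = klrec.id
                bundle.kinetic_laws.append(klrec)
                plist = _child(kl, "listOfParameters")
                for j, p in (
                    [] if plist is None else enumerate(_children(plist, "parameter"))
                ):
                    bundle.kinetic_law_parameters.append(
                        KineticLawParameterRecord(
                            id=fresh("kineticLawParameter", f"{sid}/kl/{p.get('id')}/{j}"),
                            kinetic_law_id=klrec.id,
                            sbml_id=p.get("id", ""),
                            name=p.get("name"),
                            value=_float(p, "value"),
                            units_id=unit_by_sbml.get(p.get("units", "")),
                        )
                    )

    # --- events ----------------------------------------------------------
    lo = _child(model_el, "listOfEvents")
    if lo is not None:
        for i, el in enumerate(_children(lo, "event")):
            sid = el.get("id")
            register(sid)
            ev = EventRecord(
                id=fresh("event", sid, i),
                model_id=model.id,
                sbml_id=sid,
                name=el.get("name"),
                **_SbaseReader.fields(el),
            )
            bundle.events.append(ev)
            trig = _child(el, "trigger")
            if trig is not None:
                bundle.event_triggers.append(
                    EventTriggerRecord(
                        id=fresh("eventTrigger", None, i),
                        event_id=ev.id,
                        mathml=_serialize(_child(trig, "math")),
                        **_SbaseReader.fields(trig),
                    )
                )
            delay = _child(el, "delay")
            if delay is not None:
                bundle.event_delays.append(
                    EventDelayRecord(
                        id=fresh("eventDelay", None, i),
                        event_id=ev.id,
                        mathml=_serialize(_child(delay, "math")),
                        **_SbaseReader.fields(delay),
                    )
                )
            alist = _child(el, "listOfEventAssignments")
            for j, ea in (
                [] if alist is None else enumerate(_children(alist, "eventAssignment"))
            ):
                bundle.event_assignments.append(
                    EventAssignmentRecord(
                        id=fresh("eventAssignment", None, i * 1000 + j),
                        event_id=ev.id,
                        variable=ea.get("variable", ""),
                        mathml=_serialize(_child(ea, "math")),
                        **_SbaseReader.fields(ea),
                    )
                )

    return bundle


_CI_RE = re.compile(r"<(?:\w+:)?ci[^>]*>\s*([^<\s][^<]*?)\s*</(?:\w+:)?ci>")


def mathml_identifiers(mathml: str | None) -> list[str]:
    """Identifiers (``<ci>`` leaves) of a MathML fragment, in document order."""
    if not mathml:
        return []
    seen: set[str] = set()
    out: list[str] = []
    for m in _CI_RE.finditer(mathml):
        sym = m.group(1).strip()
        if sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def resolve_function_references(
    expr: MathExpression,
    functions: list[FunctionDefinitionRecord],
    *,
    species: dict[str, str] | None = None,
    parameters: dict[str, str] | None = None,
    compartments: dict[str, str] | None = None,
) -> MathExpression:
    """Classify every MathML identifier of *expr* and populate its arguments.

    Identifiers matching a function definition ``sbml_id`` become arguments
    of kind ``function`` carrying the function's internal id; the rest are
    classified species / parameter / compartment by lookup in the optional
    maps (sbml_id -> internal id); anything else is flagged ``unresolved``.
    Unresolved identifiers are reported, never fatal.
    """
    fn_by_sbml = {f.sbml_id: f.id for f in functions}
    species = species or {}
    parameters = parameters or {}
    compartments = compartments or {}
    args: list[MathArgument] = []
    for sym in mathml_identifiers(expr.mathml):
        if sym in fn_by_sbml:
            args.append(
                MathArgument(
                    symbol=sym,
                    kind=ArgumentKind.FUNCTION,
                    function_id=fn_by_sbml[sym],
                )
            )
        elif sym in species:
            args.append(MathArgument(symbol=sym, kind=ArgumentKind.SPECIES))
        elif sym in parameters:
            args.append(MathArgument(symbol=sym, kind=ArgumentKind.PARAMETER))
        elif sym in compartments:
            args.append(MathArgument(symbol=sym, kind=ArgumentKind.COMPARTMENT))
        else:
            args.append(MathArgument(symbol=sym, kind=ArgumentKind.UNRESOLVED))
    expr.arguments = args
    return expr


def seed_base_units(id_factory: IdFactory | None = None) -> list[UnitDefinitionRecord]:
    """The built-in base-unit dimension, seeded before any ingest.

    Base units carry no model id; user-specified units reference them and
    only them.
    """
    ids = id_factory or IdFactory("base-units", deterministic=True)
    return [
        UnitDefinitionRecord(
            id=ids.new_id("baseUnit", kind),
            sbml_id=kind,
            name=kind,
            model_id=None,
        )
        for kind in sorted(BASE_UNIT_KINDS)
    ]


def normalize_unit_definitions(
    bundle: ModelBundle,
) -> tuple[list[UnitDefinitionRecord], list[UnitDefinitionRecord]]:
    """Partition unit definitions into (base, user) and validate compositions.

    User units must be compositions of built-in base units only: a user unit
    defined in terms of another user unit is rejected.

    Raises
    ------
    ValidationError
        if a composition row references a non-base unit kind.
    """
    from .errors import ValidationError

    base = seed_base_units()
    user = []
    for ud in bundle.unit_definitions:
        if ud.model_id is None:
            continue
        user.append(ud)
    rows_by_ud: dict[str, list[UnitRecord]] = {}
    for row in bundle.units:
        rows_by_ud.setdefault(row.unit_definition_id, []).append(row)
    for ud in user:
        for row in rows_by_ud.get(ud.id, []):
            if row.base_unit_kind not in BASE_UNIT_KINDS:
                raise ValidationError(
                    f"unit {ud.sbml_id!r}: composition references "
                    f"{row.base_unit_kind!r}, which is not a built-in base unit "
                    "(user units cannot build on user units)"
                )
    return base, user
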