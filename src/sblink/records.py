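"""Entity records for SBML-derived kinetic models.

Every record except :class:`DataSourceRecord` extends :class:`SbaseRecord`,
mirroring the single-inheritance data model in which one ``Sbase`` row (id,
metaId, sboTerm, notes, annotation) backs each concrete entity row.  Internal
``id`` values are opaque, globally unique identifiers generated at ingest
time; the original SBML ``id`` attribute is preserved separately as
``sbml_id`` because for most model elements it is the only meaningful name.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from enum import Enum


class ReactionSpeciesRole(str, Enum):
    """Participant roles of a species in a reaction (SBML Level 2 kinds)."""

    REACTANT = "reactant"
    PRODUCT = "product"
    MODIFIER = "modifier"


class RuleType(str, Enum):
    ALGEBRAIC = "algebraic"
    ASSIGNMENT = "assignment"
    RATE = "rate"


class ArgumentKind(str, Enum):
    """Classification of an identifier appearing in a MathML expression."""

    SPECIES = "species"
    PARAMETER = "parameter"
    COMPARTMENT = "compartment"
    FUNCTION = "function"
    UNRESOLVED = "unresolved"


#: SBML Level 2 built-in base units.  User-defined units are compositions of
#: these and only these; the base dimension is seeded before any ingest.
BASE_UNIT_KINDS: frozenset[str] = frozenset(
    {
        "ampere", "becquerel", "candela", "celsius", "coulomb",
        "dimensionless", "farad", "gram", "gray", "henry", "hertz", "item",
        "joule", "katal", "kelvin", "kilogram", "litre", "lumen", "lux",
        "metre", "mole", "newton", "ohm", "pascal", "radian", "second",
        "siemens", "sievert", "steradian", "tesla", "volt", "watt", "weber",
    }
)


class IdFactory:
    """Generates opaque internal identifiers.

    By default ids are random UUID4 strings.  In deterministic mode each id
    is a UUID5 derived from ``(data_source, kind, key)`` so that repeated
    ingests of the same document yield identical ids (reproducible tests,
    idempotent re-ingest).
    """

    _NS = uuid.UUID("8c5c3e4e-1d5a-4b73-9f5e-2f6a62d1b9a0")

    def __init__(self, data_source: str = "", deterministic: bool = False):
        self.data_source = data_source
        self.deterministic = deterministic
        self._counter = 0

    def new_id(self, kind: str, key: str | None = None) -> str:
        if self.deterministic:
            if key is None:
                self._counter += 1
                key = f"#{self._counter}"
            return str(
                uuid.uuid5(self._NS, f"{self.data_source}/{kind}/{key}")
            )
        return str(uuid.uuid4())


@dataclass(kw_only=True)
class SbaseRecord:
    id: str
    meta_id: str | None = None
    sbo_term: str | None = None
    notes: str | None = None
    annotation: str | None = None


@dataclass(kw_only=True)
class DataSourceRecord:
    """A systems-biology data source. ``name`` is a candidate key."""

    id: str
    name: str
    url: str | None = None


@dataclass(kw_only=True)
class ModelRecord(SbaseRecord):
    sbml_id: str
    name: str | None = None
    sbml_level: int = 2
    sbml_version: int = 1
    data_source_id: str = ""
    sbml_file: str = ""


@dataclass(kw_only=True)
class CompartmentTypeRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None


@dataclass(kw_only=True)
class SpeciesTypeRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None


@dataclass(kw_only=True)
class CompartmentRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None
    compartment_type_id: str | None = None
    spatial_dimensions: int | None = None
    size: float | None = None
    units_id: str | None = None
    compartment_class_id: str | None = None
    outside: str | None = None
    constant: bool = True


@dataclass(kw_only=True)
class CompartmentClassRecord:
    """Biologically curated compartment classification; roots have null parent."""

    id: str
    name: str
    parent_id: str | None = None


@dataclass(kw_only=True)
class CompartmentClassDictionaryRecord:
    compartment_name: str  # unique
    compartment_class_id: str = ""


@dataclass(kw_only=True)
class SpeciesRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None
    species_type_id: str | None = None
    compartment_id: str | None = None
    initial_amount: float | None = None
    initial_concentration: float | None = None
    substance_units_id: str | None = None
    has_only_substance_units: bool = False
    boundary_condition: bool = False
    charge: int | None = None
    constant: bool = False

    def __post_init__(self) -> None:
        if self.initial_amount is not None and self.initial_concentration is not None:
            raise ValueError(
                f"species {self.sbml_id!r}: initialAmount and "
                "initialConcentration are mutually exclusive"
            )


@dataclass(kw_only=True)
class ParameterRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None
    value: float | None = None
    units_id: str | None = None
    constant: bool = True


@dataclass(kw_only=True)
class ReactionRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None
    reversible: bool = True  # SBML default
    fast: bool = False
    kinetic_law_id: str | None = None


@dataclass(kw_only=True)
class ReactionSpeciesRecord(SbaseRecord):
    reaction_id: str
    species_id: str
    role: ReactionSpeciesRole
    stoichiometry: float | None = None
    stoichiometry_math: str | None = None  # MathML text
    sbml_id: str | None = None
    name: str | None = None


@dataclass(kw_only=True)
class KineticLawRecord(SbaseRecord):
    reaction_id: str
    mathml: str | None = None
    time_units_id: str | None = None
    substance_units_id: str | None = None


@dataclass(kw_only=True)
class KineticLawParameterRecord(SbaseRecord):
    kinetic_law_id: str
    sbml_id: str
    name: str | None = None
    value: float | None = None
    units_id: str | None = None


@dataclass(kw_only=True)
class UnitDefinitionRecord(SbaseRecord):
    sbml_id: str
    name: str | None = None
    #: absent for the built-in base units, set for user units
    model_id: str | None = None


@dataclass(kw_only=True)
class UnitRecord:
    """One composition row of a user unit in terms of a base unit."""

    unit_definition_id: str
    base_unit_kind: str
    exponent: float = 1.0
    scale: int = 0
    multiplier: float = 1.0


@dataclass(kw_only=True)
class FunctionDefinitionRecord(SbaseRecord):
    model_id: str
    sbml_id: str
    name: str | None = None
    mathml: str | None = None


@dataclass(kw_only=True)
class RuleRecord(SbaseRecord):
    model_id: str
    rule_type: RuleType
    variable: str | None = None
    mathml: str | None = None


@dataclass(kw_only=True)
class ConstraintRecord(SbaseRecord):
    model_id: str
    mathml: str | None = None
    message: str | None = None


@dataclass(kw_only=True)
class InitialAssignmentRecord(SbaseRecord):
    model_id: str
    symbol: str
    mathml: str | None = None


@dataclass(kw_only=True)
class EventRecord(SbaseRecord):
    model_id: str
    sbml_id: str | None = None
    name: str | None = None


@dataclass(kw_only=True)
class EventTriggerRecord(SbaseRecord):
    event_id: str
    mathml: str | None = None


@dataclass(kw_only=True)
class EventDelayRecord(SbaseRecord):
    event_id: str
    mathml: str | None = None


@dataclass(kw_only=True)
class EventAssignmentRecord(SbaseRecord):
    event_id: str
    variable: str
    mathml: str | None = None


@dataclass(kw_only=True)
class AuthorRecord:
    id: str
    name: str | None = None
    surname: str | None = None
    email: str | None = None
    org_name: str | None = None


@dataclass(kw_only=True)
class DesignedByRecord:
    id: str
    model_key: str = ""
    author_key: str = ""


@dataclass(kw_only=True)
class ModelMetadataRecord:
    id: str
    model_name: str | None = None
    publication_id: str | None = None
    creation_date: str | None = None
    modification_date: str | None = None
    notes: str | None = None


@dataclass(kw_only=True)
class ModelLayoutRecord:
    """Opaque curated visualization layout for a model."""

    id: str
    layout: str = ""


@dataclass(kw_only=True)
class MathArgument:
    symbol: str
    kind: ArgumentKind
    function_id: str | None = None


@dataclass(kw_only=True)
class MathExpression:
    """A MathML expression plus its classified identifier arguments.

    ``function_id`` on an argument accommodates references to user-defined
    functions inside kinetic laws, rules etc. of the same model.
    """

    owner_id: str
    mathml: str
    arguments: list[MathArgument] = field(default_factory=list)


@dataclass(kw_only=True)
class ModelBundle:
    """Everything parsed from one SBML document."""

    model: ModelRecord
    compartments: list[CompartmentRecord] = field(default_factory=list)
    compartment_types: list[CompartmentTypeRecord] = field(default_factory=list)
    species_types: list[SpeciesTypeRecord] = field(default_factory=list)
    species: list[SpeciesRecord] = field(default_factory=list)
    parameters: list[ParameterRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    reaction_species: list[ReactionSpeciesRecord] = field(default_factory=list)
    kinetic_laws: list[KineticLawRecord] = field(default_factory=list)
    kinetic_law_parameters: list[KineticLawParameterRecord] = field(default_factory=list)
    unit_definitions: list[UnitDefinitionRecord] = field(default_factory=list)
    units: list[UnitRecord] = field(default_factory=list)
    function_definitions: list[FunctionDefinitionRecord] = field(default_factory=list)
    rules: list[RuleRecord] = field(default_factory=list)
    constraints: list[ConstraintRecord] = field(default_factory=list)
    initial_assignments: list[InitialAssignmentRecord] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)
    event_triggers: list[EventTriggerRecord] = field(default_factory=list)
    event_delays: list[EventDelayRecord] = field(default_factory=list)
    event_assignments: list[EventAssignmentRecord] = field(default_factory=list)

    def all_sbase_records(self) -> list[SbaseRecord]:
        """All records carrying the Sbase base fields, model first."""
        out: list[SbaseRecord] = [self.model]
        for group in (
            self.compartment_types, self.species_types, self.compartments,
            self.species, self.parameters, self.reactions,
            self.reaction_species, self.kinetic_laws,
            self.kinetic_law_parameters, self.unit_definitions,
            self.function_definitions, self.rules, self.constraints,
            self.initial_assignments, self.events, self.event_triggers,
            self.event_delays, self.event_assignments,
        ):
            out.extend(group)
        return out

    def counts(self) -> dict[str, int]:
        return {
            "compartments": len(self.compartments),
            "species": len(self.species),
            "reactions": len(self.reactions),
            "reaction_species": len(self.reaction_species),
            "parameters": len(self.parameters),
            "kinetic_laws": len(self.kinetic_laws),
            "unit_definitions": len(self.unit_definitions),
            "function_definitions": len(self.function_definitions),
            "rules": len(self.rules),
            "events": len(self.events),
        }
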