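"""Embedded relational store behind a single-point-of-contact wrapper.

All persistence flows through :class:`Store`: callers never see SQL strings,
only per-table accessor methods, and exactly one live connection exists per
database file (singleton contract).  Small dimension tables — participant
roles, rule types, qualifier names and the like — are cached fully in
memory and rebuilt on any write to a cached table, so dimension lookups
during query processing are main-memory joins rather than repeated
disk-based joins.  The cache is a pure optimization: every query returns
identical results with the cache disabled.
"""

from __future__ import annotations

import sqlite3
from importlib import resources
from pathlib import Path

from .errors import BusyError, IntegrityError, LookupFailure
from .miriam import PREFILLED_QUALIFIERS, AnnotationLink
from .nodecodes import Labeling, code_str
from .pathway import PROCESS_ENTITY_ROLES, PathwayStore
from .records import ModelBundle, MathExpression
from .sbml import canonicalize_mathml, seed_base_units

#: The twelve dimension tables resident in the in-memory cache.
CACHED_DIMENSION_TABLES = (
    "Attribute", "EntityName", "GraphNode", "MolecularEntityType", "NameId",
    "NameType", "PathwaysType", "ProcessEntityRole", "ReactionSpeciesRole",
    "RnaType", "RuleType", "UnitDefinition",
)

_MOLECULAR_ENTITY_TYPES = ("compound", "glycan", "drug", "enzyme")


def _b(v: bool | None) -> int | None:
    return None if v is None else int(v)


class Store:
    """Wrapper over one embedded SQLite database file.

    Use :meth:`Store.open`; constructing directly bypasses the one-live-
    connection-per-file contract.
    """

    _instances: dict[str, "Store"] = {}

    def __init__(self, path: str | Path, *, cache_enabled: bool = True):
        self.path = str(Path(path).resolve()) if path != ":memory:" else ":memory:"
        self._conn = sqlite3.connect(self.path)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA foreign_keys = ON")
        self.cache_enabled = cache_enabled
        self.read_count = 0  # instrumented: SELECTs actually sent to the engine
        self._dimension_cache: dict[str, dict] = {}
        self._create_schema()
        self._seed_dimensions()
        self.reload_dimension_cache()

    # -- lifecycle -----------------------------------------------------

    @classmethod
    def open(cls, path: str | Path, *, cache_enabled: bool = True) -> "Store":
        key = str(Path(path).resolve()) if path != ":memory:" else ":memory:"
        inst = cls._instances.get(key)
        if inst is not None and key != ":memory:":
            inst.cache_enabled = cache_enabled
            return inst
        inst = cls(path, cache_enabled=cache_enabled)
        cls._instances[key] = inst
        return inst

    def close(self) -> None:
        self._conn.close()
        self._instances.pop(self.path, None)

    # -- low-level helpers (private: no SQL leaks to callers) ----------

    def _execute(self, sql: str, params=()) -> sqlite3.Cursor:
        try:
            return self._conn.execute(sql, params)
        except sqlite3.OperationalError as exc:
            if "locked" in str(exc) or "busy" in str(exc):
                raise BusyError(str(exc)) from exc
            raise
        except sqlite3.IntegrityError as exc:
            raise IntegrityError(str(exc)) from exc

    def _select(self, sql: str, params=()) -> list[sqlite3.Row]:
        self.read_count += 1
        return self._execute(sql, params).fetchall()

    def _create_schema(self) -> None:
        ddl = resources.files("sblink").joinpath("schema.sql").read_text()
        self._conn.executescript(ddl)
        self._conn.execute("PRAGMA foreign_keys = ON")

    def _seed_dimensions(self) -> None:
        with self._conn:
            for name in ("reactant", "product", "modifier"):
                self._execute(
                    "INSERT OR IGNORE INTO ReactionSpeciesRole (name) VALUES (?)",
                    (name,),
                )
            for name in ("algebraic", "assignment", "rate"):
                self._execute(
                    "INSERT OR IGNORE INTO RuleType (name) VALUES (?)", (name,)
                )
            for name in PROCESS_ENTITY_ROLES:
                self._execute(
                    "INSERT OR IGNORE INTO ProcessEntityRole (name) VALUES (?)",
                    (name,),
                )
            for name in _MOLECULAR_ENTITY_TYPES:
                self._execute(
                    "INSERT OR IGNORE INTO MolecularEntityType (name) VALUES (?)",
                    (name,),
                )
            for name in PREFILLED_QUALIFIERS:
                self._execute(
                    "INSERT OR IGNORE INTO AnnotationQualifier (name) VALUES (?)",
                    (name,),
                )
            # built-in base units exist before any document is ingested
            for rec in seed_base_units():
                self._execute(
                    "INSERT OR IGNORE INTO Sbase (id) VALUES (?)", (rec.id,)
                )
                self._execute(
                    "INSERT OR IGNORE INTO UnitDefinition "
                    "(id, sbmlId, name, modelId) VALUES (?, ?, ?, NULL)",
                    (rec.id, rec.sbml_id, rec.name),
                )
                self._execute(
                    "INSERT OR IGNORE INTO SbaseIndex (sbaseId, modelId, kind) "
                    "VALUES (?, '__base__', 'unitDefinition')",
                    (rec.id,),
                )

    # -- dimension cache ------------------------------------------------

    def reload_dimension_cache(self) -> None:
        """(Re)load every cached dimension table fully into memory."""
        cache: dict[str, dict] = {}
        for table in CACHED_DIMENSION_TABLES:
            if table == "UnitDefinition":
                rows = self._select(
                    "SELECT id, sbmlId, name, modelId FROM UnitDefinition"
                )
                cache[table] = {r["id"]: dict(r) for r in rows}
            else:
                rows = self._select(f"SELECT id, name FROM {table}")
                cache[table] = {r["id"]: r["name"] for r in rows}
            cache[table + "/by_name"] = {
                (v["sbmlId"] if isinstance(v, dict) else v): k
                for k, v in cache[table].items()
            }
        self._dimension_cache = cache

    def _invalidate_cache(self, table: str) -> None:
        if table in CACHED_DIMENSION_TABLES:
            self.reload_dimension_cache()

    def dimension_rows(self, table: str) -> dict:
        """Primary-key lookup map for a cached dimension table.

        With the cache enabled this performs zero store reads.
        """
        if table not in CACHED_DIMENSION_TABLES:
            raise LookupFailure(f"{table!r} is not a cached dimension table")
        if self.cache_enabled:
            return self._dimension_cache[table]
        if table == "UnitDefinition":
            rows = self._select("SELECT id, sbmlId, name, modelId FROM UnitDefinition")
            return {r["id"]: dict(r) for r in rows}
        rows = self._select(f"SELECT id, name FROM {table}")
        return {r["id"]: r["name"] for r in rows}

    def _dim_id(self, table: str, name: str) -> int | None:
        if self.cache_enabled:
            return self._dimension_cache[table + "/by_name"].get(name)
        rows = self._select(f"SELECT id FROM {table} WHERE name = ?", (name,))
        return rows[0]["id"] if rows else None

    def qualifier_id(self, name: str) -> int:
        """Qualifier dimension id; non-prefilled names insert on first use."""
        rows = self._select(
            "SELECT id FROM AnnotationQualifier WHERE name = ?", (name,)
        )
        if rows:
            return rows[0]["id"]
        with self._conn:
            cur = self._execute(
                "INSERT INTO AnnotationQualifier (name) VALUES (?)", (name,)
            )
        return cur.lastrowid

    def qualifier_name(self, qid: int) -> str:
        rows = self._select(
            "SELECT name FROM AnnotationQualifier WHERE id = ?", (qid,)
        )
        if not rows:
            raise LookupFailure(f"unknown qualifier id {qid}")
        return rows[0]["name"]

    def role_id(self, name: str) -> int:
        rid = self._dim_id("ReactionSpeciesRole", name)
        if rid is None:
            raise LookupFailure(f"unknown reaction-species role {name!r}")
        return rid

    def add_dimension_row(self, table: str, name: str) -> int:
        """Insert a row into a dimension table (cache rebuilds on write)."""
        with self._conn:
            cur = self._execute(
                f"INSERT INTO {table} (name) VALUES (?)", (name,)
            )
        self._invalidate_cache(table)
        return cur.lastrowid

    # -- data sources ---------------------------------------------------

    def ensure_data_source(self, name: str, url: str | None = None) -> str:
        rows = self._select("SELECT id FROM DataSource WHERE name = ?", (name,))
        if rows:
            return rows[0]["id"]
        ds_id = f"ds-{name}"
        with self._conn:
            self._execute(
                "INSERT INTO DataSource (id, name, url) VALUES (?, ?, ?)",
                (ds_id, name, url),
            )
        return ds_id

    # -- pathway-side ingestion ----------------------------------------

    def persist_pathway_store(self, pstore: PathwayStore) -> None:
        """Load all pathway-side entities into their tables."""
        type_ids = {
            v: k for k, v in self.dimension_rows("MolecularEntityType").items()
        }
        role_ids = {
            v: k for k, v in self.dimension_rows("ProcessEntityRole").items()
        }
        with self._conn:
            for me in pstore.molecular_entities.values():
                self._execute(
                    "INSERT OR REPLACE INTO molecular_entities (id, name, typeId) "
                    "VALUES (?, ?, ?)",
                    (me.id, me.name, type_ids.get(me.type)),
                )
                for ns, xid in sorted(me.external_ids):
                    self._execute(
                        "INSERT OR IGNORE INTO molecular_entity_xrefs VALUES (?, ?, ?)",
                        (me.id, ns, xid),
                    )
            for proc in pstore.processes.values():
                self._execute(
                    "INSERT OR REPLACE INTO processes (id, name) VALUES (?, ?)",
                    (proc.id, proc.name),
                )
                for ns, xid in sorted(proc.external_ids):
                    self._execute(
                        "INSERT OR IGNORE INTO process_xrefs VALUES (?, ?, ?)",
                        (proc.id, ns, xid),
                    )
                for me_id, role in proc.participants:
                    self._execute(
                        "INSERT INTO process_participants VALUES (?, ?, ?)",
                        (proc.id, me_id, role_ids[role]),
                    )
            for og in pstore.organism_groups.values():
                self._execute(
                    "INSERT OR REPLACE INTO organism_groups (id, name) VALUES (?, ?)",
                    (og.id, og.name),
                )
                for tax in sorted(og.ncbi_taxonomy_ids):
                    self._execute(
                        "INSERT OR IGNORE INTO organism_group_taxa VALUES (?, ?)",
                        (og.id, tax),
                    )
            for pw in pstore.pathways.values():
                self._execute(
                    "INSERT OR REPLACE INTO pathways (id, name, organismGroupId) "
                    "VALUES (?, ?, ?)",
                    (pw.id, pw.name, pw.organism_group_id),
                )
                for ns, xid in sorted(pw.external_ids):
                    self._execute(
                        "INSERT OR IGNORE INTO pathway_xrefs VALUES (?, ?, ?)",
                        (pw.id, ns, xid),
                    )
                for proc_id in pw.process_ids:
                    self._execute(
                        "INSERT OR IGNORE INTO pathway_processes VALUES (?, ?)",
                        (pw.id, proc_id),
                    )
            for term in pstore.go_terms.values():
                self._execute(
                    "INSERT OR REPLACE INTO go_terms (id, name) VALUES (?, ?)",
                    (term.go_id, term.name),
                )
            for term in pstore.go_terms.values():
                for parent in term.parent_ids:
                    self._execute(
                        "INSERT OR IGNORE INTO go_term_parents VALUES (?, ?)",
                        (term.go_id, parent),
                    )
            for ec in pstore.ec_numbers.values():
                self._execute(
                    "INSERT OR REPLACE INTO ec_numbers VALUES (?, ?, ?)",
                    (ec.ec_number, ec.name, ec.node_code),
                )

    def persist_go_labeling(self, labeling: Labeling) -> int:
        """Store precomputed NodeCodes for GO terms (GONodeCodes rows)."""
        n = 0
        with self._conn:
            self._execute("DELETE FROM GONodeCodes")
            for node in labeling.real_nodes:
                for code in sorted(labeling.nc[node]):
                    self._execute(
                        "INSERT OR IGNORE INTO GONodeCodes (goId, nodeCode) "
                        "VALUES (?, ?)",
                        (str(node), code_str(code)),
                    )
                    n += 1
        return n

    # -- model-side ingestion ------------------------------------------

    def persist_model_bundle(
        self, bundle: ModelBundle, links: list[AnnotationLink] | None = None
    ) -> str:
        """Persist a parsed model and its extracted annotation links.

        One row per record; the Sbase row is created first and entity rows
        reference it.  Re-ingesting the same (data source, sbmlId) replaces
        the prior version atomically.
        """
        links = links or []
        model = bundle.model
        existing = self._select(
            "SELECT id FROM Model WHERE dataSourceId = ? AND sbmlId = ?",
            (model.data_source_id, model.sbml_id),
        )
        qual_ids = {
            link.qualifier.value: self.qualifier_id(link.qualifier.value)
            for link in links
        }
        role_ids = {
            name: self.role_id(name) for name in ("reactant", "product", "modifier")
        }
        rule_type_ids = {
            v: k for k, v in self.dimension_rows("RuleType").items()
        }
        try:
            with self._conn:
                if existing:
                    self._delete_model_rows(existing[0]["id"])
                index_rows: list[tuple[str, str]] = []

                def sbase(rec, kind: str) -> None:
                    self._execute(
                        "INSERT INTO Sbase (id, metaId, sboTerm, notes, annotation) "
                        "VALUES (?, ?, ?, ?, ?)",
                        (rec.id, rec.meta_id, rec.sbo_term, rec.notes, rec.annotation),
                    )
                    index_rows.append((rec.id, kind))

                sbase(model, "model")
                self._execute(
                    "INSERT INTO Model (id, sbmlId, name, sbmlLevel, sbmlVersion, "
                    "dataSourceId, sbmlFile) VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (model.id, model.sbml_id, model.name, model.sbml_level,
                     model.sbml_version, model.data_source_id, model.sbml_file),
                )
                for rec in bundle.unit_definitions:
                    sbase(rec, "unitDefinition")
                    self._execute(
                        "INSERT INTO UnitDefinition (id, sbmlId, name, modelId) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.sbml_id, rec.name, rec.model_id),
                    )
                for row in bundle.units:
                    self._execute(
                        "INSERT INTO UnitComposition (unitDefinitionId, baseUnitKind,"
                        " exponent, scale, multiplier) VALUES (?, ?, ?, ?, ?)",
                        (row.unit_definition_id, row.base_unit_kind,
                         row.exponent, row.scale, row.multiplier),
                    )
                for rec in bundle.compartment_types:
                    sbase(rec, "compartmentType")
                    self._execute(
                        "INSERT INTO CompartmentType (id, modelId, sbmlId, name) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name),
                    )
                for rec in bundle.species_types:
                    sbase(rec, "speciesType")
                    self._execute(
                        "INSERT INTO SpeciesType (id, modelId, sbmlId, name) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name),
                    )
                for rec in bundle.compartments:
                    sbase(rec, "compartment")
                    self._execute(
                        "INSERT INTO Compartment (id, modelId, sbmlId, name, "
                        "compartmentTypeId, spatialDimensions, size, unitsId, "
                        "compartmentClassId, outside, constant) "
                        "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name,
                         rec.compartment_type_id, rec.spatial_dimensions, rec.size,
                         rec.units_id, rec.compartment_class_id, rec.outside,
                         _b(rec.constant)),
                    )
                for rec in bundle.species:
                    sbase(rec, "species")
                    self._execute(
                        "INSERT INTO Species (id, modelId, sbmlId, name, "
                        "speciesTypeId, compartmentId, initialAmount, "
                        "initialConcentration, substanceUnitsId, "
                        "hasOnlySubstanceUnits, boundaryCondition, charge, constant)"
                        " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name,
                         rec.species_type_id, rec.compartment_id,
                         rec.initial_amount, rec.initial_concentration,
                         rec.substance_units_id, _b(rec.has_only_substance_units),
                         _b(rec.boundary_condition), rec.charge, _b(rec.constant)),
                    )
                for rec in bundle.parameters:
                    sbase(rec, "parameter")
                    self._execute(
                        "INSERT INTO Parameter (id, modelId, sbmlId, name, value, "
                        "unitsId, constant) VALUES (?, ?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name, rec.value,
                         rec.units_id, _b(rec.constant)),
                    )
                for rec in bundle.function_definitions:
                    sbase(rec, "functionDefinition")
                    self._execute(
                        "INSERT INTO FunctionDefinition (id, modelId, sbmlId, name, "
                        "math) VALUES (?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name, rec.mathml),
                    )
                for rec in bundle.reactions:
                    sbase(rec, "reaction")
                    self._execute(
                        "INSERT INTO Reaction (id, modelId, sbmlId, name, "
                        "reversible, fast, kineticLawId) VALUES (?, ?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name,
                         _b(rec.reversible), _b(rec.fast), rec.kinetic_law_id),
                    )
                for rec in bundle.kinetic_laws:
                    sbase(rec, "kineticLaw")
                    self._execute(
                        "INSERT INTO KineticLaw (id, reactionId, math, timeUnitsId, "
                        "substanceUnitsId) VALUES (?, ?, ?, ?, ?)",
                        (rec.id, rec.reaction_id, rec.mathml, rec.time_units_id,
                         rec.substance_units_id),
                    )
                for rec in bundle.kinetic_law_parameters:
                    sbase(rec, "kineticLawParameter")
                    self._execute(
                        "INSERT INTO KineticLawParameter (id, kineticLawId, sbmlId, "
                        "name, value, unitsId) VALUES (?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.kinetic_law_id, rec.sbml_id, rec.name,
                         rec.value, rec.units_id),
                    )
                for rec in bundle.reaction_species:
                    sbase(rec, "reactionSpecies")
                    self._execute(
                        "INSERT INTO ReactionSpecies (id, reactionId, speciesId, "
                        "roleId, stoichiometry, stoichiometryMath, sbmlId, name) "
                        "VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                        (rec.id, rec.reaction_id, rec.species_id,
                         role_ids[rec.role.value], rec.stoichiometry,
                         rec.stoichiometry_math, rec.sbml_id, rec.name),
                    )
                for rec in bundle.rules:
                    sbase(rec, "rule")
                    self._execute(
                        "INSERT INTO Rule (id, modelId, ruleTypeId, variable, math) "
                        "VALUES (?, ?, ?, ?, ?)",
                        (rec.id, rec.model_id, rule_type_ids[rec.rule_type.value],
                         rec.variable, rec.mathml),
                    )
                for rec in bundle.constraints:
                    sbase(rec, "constraint")
                    self._execute(
                        'INSERT INTO "Constraint" (id, modelId, math, message) '
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.mathml, rec.message),
                    )
                for rec in bundle.initial_assignments:
                    sbase(rec, "initialAssignment")
                    self._execute(
                        "INSERT INTO InitialAssignment (id, modelId, symbol, math) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.symbol, rec.mathml),
                    )
                for rec in bundle.events:
                    sbase(rec, "event")
                    self._execute(
                        "INSERT INTO Event (id, modelId, sbmlId, name) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.model_id, rec.sbml_id, rec.name),
                    )
                for rec in bundle.event_triggers:
                    sbase(rec, "eventTrigger")
                    self._execute(
                        "INSERT INTO EventTrigger (id, eventId, math) VALUES (?, ?, ?)",
                        (rec.id, rec.event_id, rec.mathml),
                    )
                for rec in bundle.event_delays:
                    sbase(rec, "eventDelay")
                    self._execute(
                        "INSERT INTO EventDelay (id, eventId, math) VALUES (?, ?, ?)",
                        (rec.id, rec.event_id, rec.mathml),
                    )
                for rec in bundle.event_assignments:
                    sbase(rec, "eventAssignment")
                    self._execute(
                        "INSERT INTO EventAssignment (id, eventId, variable, math) "
                        "VALUES (?, ?, ?, ?)",
                        (rec.id, rec.event_id, rec.variable, rec.mathml),
                    )
                for sbase_id, kind in index_rows:
                    self._execute(
                        "INSERT INTO SbaseIndex (sbaseId, modelId, kind) "
                        "VALUES (?, ?, ?)",
                        (sbase_id, model.id, kind),
                    )
                for link in links:
                    self._execute(
                        "INSERT INTO AnnotationLink (sbaseId, qualifierId, family, "
                        "namespace, externalId, rawUrn) VALUES (?, ?, ?, ?, ?, ?)",
                        (link.subject_sbase_id, qual_ids[link.qualifier.value],
                         link.family.value, link.namespace, link.external_id,
                         link.raw_urn),
                    )
        except sqlite3.IntegrityError as exc:  # pragma: no cover - rewrapped
            raise IntegrityError(str(exc)) from exc
        self._invalidate_cache("UnitDefinition")
        return model.id

    def persist_math_arguments(self, expr: MathExpression) -> None:
        with self._conn:
            for arg in expr.arguments:
                self._execute(
                    "INSERT INTO MathArgument (ownerId, symbol, kind, functionId) "
                    "VALUES (?, ?, ?, ?)",
                    (expr.owner_id, arg.symbol, arg.kind.value, arg.function_id),
                )

    # -- deletion -------------------------------------------------------

    def _delete_model_rows(self, model_id: str) -> None:
        rows = self._select(
            "SELECT sbaseId FROM SbaseIndex WHERE modelId = ?", (model_id,)
        )
        for row in rows:
            self._execute("DELETE FROM Sbase WHERE id = ?", (row["sbaseId"],))

    def delete_model(self, model_id: str) -> int:
        """Delete a model and every dependent row; returns rows removed.

        Implements ON-DELETE-CASCADE semantics over the Sbase inheritance
        hierarchy: the model's Sbase closure is removed and engine-level
        cascades clear entity, participant, mapping and annotation rows.
        Pathway-side rows are untouched.
        """
        rows = self._select("SELECT id FROM Model WHERE id = ?", (model_id,))
        if not rows:
            raise LookupFailure(f"unknown model id {model_id!r}")
        before = self._conn.total_changes
        with self._conn:
            self._delete_model_rows(model_id)
        self._invalidate_cache("UnitDefinition")
        return self._conn.total_changes - before

    def orphan_rows(self) -> list[tuple]:
        """Foreign-key sweep: every row referencing a missing parent."""
        self.read_count += 1
        violations = [
            tuple(r) for r in self._conn.execute("PRAGMA foreign_key_check")
        ]
        # Sbase rows no longer claimed by any entity index are orphans too.
        unclaimed = self._select(
            "SELECT s.id FROM Sbase s LEFT JOIN SbaseIndex i ON s.id = i.sbaseId "
            "WHERE i.sbaseId IS NULL"
        )
        violations.extend(("Sbase", r["id"], "SbaseIndex", 0) for r in unclaimed)
        return violations

    def table_counts(self) -> dict[str, int]:
        tables = [
            r["name"]
            for r in self._select(
                "SELECT name FROM sqlite_master WHERE type = 'table' "
                "AND name NOT LIKE 'sqlite_%'"
            )
        ]
        return {
            t: self._select(f'SELECT COUNT(*) AS n FROM "{t}"')[0]["n"]
            for t in tables
        }

    # -- mapping-row accessors (used by the mapping builder) -------------

    def add_map_species_molecular_entity(
        self, species_id: str, entity_id: str, qualifier_id: int
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO MapSpeciesMolecularEntities VALUES (?, ?, ?)",
                (species_id, entity_id, qualifier_id),
            )
        return cur.rowcount > 0

    def add_map_reaction_process(
        self, reaction_id: str, process_id: str, qualifier_id: int
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO MapReactionsProcessEntities VALUES (?, ?, ?)",
                (reaction_id, process_id, qualifier_id),
            )
        return cur.rowcount > 0

    def add_map_model_pathway(
        self,
        model_id: str,
        pathway_id: str,
        qualifier_id: int,
        organism_group_id: str | None,
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO MapModelsPathways VALUES (?, ?, ?, ?)",
                (model_id, pathway_id, qualifier_id, organism_group_id),
            )
        return cur.rowcount > 0

    def add_model_organism(
        self,
        model_id: str,
        organism_group_id: str | None,
        taxonomy_id: str,
        qualifier_id: int,
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO ModelOrganism VALUES (?, ?, ?, ?)",
                (model_id, organism_group_id, taxonomy_id, qualifier_id),
            )
        return cur.rowcount > 0

    def add_map_sbase_go(
        self, sbase_id: str, go_id: str, qualifier_id: int
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO MapSbaseGO VALUES (?, ?, ?)",
                (sbase_id, go_id, qualifier_id),
            )
        return cur.rowcount > 0

    def add_map_reaction_ec(
        self, reaction_id: str, ec_number: str, qualifier_id: int
    ) -> bool:
        with self._conn:
            cur = self._execute(
                "INSERT OR IGNORE INTO MapReactionECNumber VALUES (?, ?, ?)",
                (reaction_id, ec_number, qualifier_id),
            )
        return cur.rowcount > 0

    # -- generic readers used across modules ----------------------------

    def sbase_kind(self, sbase_id: str) -> tuple[str, str] | None:
        """(kind, modelId) of an Sbase row, or None if unindexed."""
        rows = self._select(
            "SELECT kind, modelId FROM SbaseIndex WHERE sbaseId = ?", (sbase_id,)
        )
        return (rows[0]["kind"], rows[0]["modelId"]) if rows else None

    def annotation_links(self) -> list[sqlite3.Row]:
        return self._select(
            "SELECT l.sbaseId, q.name AS qualifier, l.family, l.namespace, "
            "l.externalId, l.rawUrn, i.kind, i.modelId "
            "FROM AnnotationLink l "
            "JOIN AnnotationQualifier q ON q.id = l.qualifierId "
            "JOIN SbaseIndex i ON i.sbaseId = l.sbaseId"
        )

    def go_term_exists(self, go_id: str) -> bool:
        return bool(self._select("SELECT 1 FROM go_terms WHERE id = ?", (go_id,)))

    def ec_number_exists(self, ec: str) -> bool:
        return bool(
            self._select("SELECT 1 FROM ec_numbers WHERE ec_number = ?", (ec,))
        )

    def pathway_exists(self, pathway_id: str) -> bool:
        return bool(self._select("SELECT 1 FROM pathways WHERE id = ?", (pathway_id,)))

    def process_exists(self, process_id: str) -> bool:
        return bool(self._select("SELECT 1 FROM processes WHERE id = ?", (process_id,)))

    def pathway_organism_group(self, pathway_id: str) -> str | None:
        rows = self._select(
            "SELECT organismGroupId FROM pathways WHERE id = ?", (pathway_id,)
        )
        return rows[0]["organismGroupId"] if rows else None

    def organism_group_of_taxon(self, taxonomy_id: str) -> str | None:
        rows = self._select(
            "SELECT organismGroupId FROM organism_group_taxa "
            "WHERE NCBITaxonomyId = ?",
            (taxonomy_id,),
        )
        return rows[0]["organismGroupId"] if rows else None

    def models(self) -> list[sqlite3.Row]:
        return self._select("SELECT id, sbmlId, name, dataSourceId FROM Model")

    def reactions_of_model(self, model_id: str) -> list[str]:
        return [
            r["id"]
            for r in self._select(
                "SELECT id FROM Reaction WHERE modelId = ?", (model_id,)
            )
        ]

    def species_of_model(self, model_id: str) -> list[str]:
        return [
            r["id"]
            for r in self._select(
                "SELECT id FROM Species WHERE modelId = ?", (model_id,)
            )
        ]

    def mapping_summary_counts(self) -> dict[str, int]:
        """Distinct-count statistics over the mapping tables."""

        def one(sql: str) -> int:
            return self._select(sql)[0][0]

        return {
            "models_total": one("SELECT COUNT(*) FROM Model"),
            "models_with_pathway_map": one(
                "SELECT COUNT(DISTINCT modelId) FROM MapModelsPathways"
            ),
            "models_with_go_annotation": one(
                "SELECT COUNT(DISTINCT i.modelId) FROM MapSbaseGO g "
                "JOIN SbaseIndex i ON i.sbaseId = g.sbaseId"
            ),
            "reactions_total": one("SELECT COUNT(*) FROM Reaction"),
            "reactions_mapped": one(
                "SELECT COUNT(DISTINCT reactionId) FROM MapReactionsProcessEntities"
            ),
            "species_total": one("SELECT COUNT(*) FROM Species"),
            "species_mapped": one(
                "SELECT COUNT(DISTINCT speciesId) FROM MapSpeciesMolecularEntities"
            ),
            "distinct_pathways_hit": one(
                "SELECT COUNT(DISTINCT pathwayId) FROM MapModelsPathways"
            ),
            "distinct_processes_hit": one(
                "SELECT COUNT(DISTINCT processId) FROM MapReactionsProcessEntities"
            ),
            "distinct_molecular_entities_hit": one(
                "SELECT COUNT(DISTINCT molecularEntityId) "
                "FROM MapSpeciesMolecularEntities"
            ),
        }

    def dump_table(self, table: str) -> list[sqlite3.Row]:
        """Full contents of one table (wrapper-level export accessor)."""
        return self._select(f'SELECT * FROM "{table}"')

    def dump_table_with_names(self, table: str) -> list[sqlite3.Row]:
        """Mapping-table rows resolved to source sbmlIds + qualifier names."""
        if table == "MapSpeciesMolecularEntities":
            return self._select(
                "SELECT m.sbmlId AS modelSbmlId, s.sbmlId AS speciesSbmlId, "
                "t.molecularEntityId, q.name AS qualifier "
                "FROM MapSpeciesMolecularEntities t "
                "JOIN Species s ON s.id = t.speciesId "
                "JOIN Model m ON m.id = s.modelId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        if table == "MapReactionsProcessEntities":
            return self._select(
                "SELECT m.sbmlId AS modelSbmlId, r.sbmlId AS reactionSbmlId, "
                "t.processId, q.name AS qualifier "
                "FROM MapReactionsProcessEntities t "
                "JOIN Reaction r ON r.id = t.reactionId "
                "JOIN Model m ON m.id = r.modelId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        if table == "MapModelsPathways":
            return self._select(
                "SELECT m.sbmlId AS modelSbmlId, t.pathwayId, "
                "t.organismGroupId, q.name AS qualifier "
                "FROM MapModelsPathways t "
                "JOIN Model m ON m.id = t.modelId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        if table == "ModelOrganism":
            return self._select(
                "SELECT m.sbmlId AS modelSbmlId, t.NCBITaxonomyId, "
                "t.organismGroupId, q.name AS qualifier "
                "FROM ModelOrganism t "
                "JOIN Model m ON m.id = t.modelId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        if table == "MapSbaseGO":
            return self._select(
                "SELECT i.modelId, i.kind, t.sbaseId, t.goId, "
                "q.name AS qualifier FROM MapSbaseGO t "
                "JOIN SbaseIndex i ON i.sbaseId = t.sbaseId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        if table == "MapReactionECNumber":
            return self._select(
                "SELECT m.sbmlId AS modelSbmlId, r.sbmlId AS reactionSbmlId, "
                "t.ecNumber, q.name AS qualifier "
                "FROM MapReactionECNumber t "
                "JOIN Reaction r ON r.id = t.reactionId "
                "JOIN Model m ON m.id = r.modelId "
                "JOIN AnnotationQualifier q ON q.id = t.qualifierId"
            )
        raise LookupFailure(f"no verbose view for table {table!r}")

    # -- built-in queries ------------------------------------------------

    def query_models_with_pathway_reactions(self, pathway_id: str) -> list[dict]:
        """Find models that contain reactions of a given pathway.

        One row per (mapped reaction x participant); the Species Name
        (Reaction Role) column joins ReactionSpecies with the cached
        ReactionSpeciesRole dimension in memory.
        """
        if not self.pathway_exists(pathway_id):
            raise LookupFailure(f"unknown pathway {pathway_id!r}")
        rows = self._select(
            "SELECT m.id AS modelId, m.sbmlId AS modelSbmlId, "
            "r.id AS reactionId, r.sbmlId AS reactionSbmlId, "
            "s.name AS speciesName, s.sbmlId AS speciesSbmlId, rs.roleId AS roleId "
            "FROM pathway_processes pp "
            "JOIN MapReactionsProcessEntities mrp ON mrp.processId = pp.processId "
            "JOIN Reaction r ON r.id = mrp.reactionId "
            "JOIN Model m ON m.id = r.modelId "
            "JOIN ReactionSpecies rs ON rs.reactionId = r.id "
            "JOIN Species s ON s.id = rs.speciesId "
            "WHERE pp.pathwayId = ? "
            "ORDER BY m.sbmlId, r.sbmlId, rs.roleId, s.sbmlId",
            (pathway_id,),
        )
        roles = self.dimension_rows("ReactionSpeciesRole")
        out = []
        for r in rows:
            d = dict(r)
            d["role"] = roles[d.pop("roleId")]  # main-memory join
            d["speciesNameWithRole"] = (
                f"{d['speciesName'] or d['speciesSbmlId']} ({d['role']})"
            )
            out.append(d)
        return out

    def query_models_with_pathway_metabolites(self, pathway_id: str) -> set[str]:
        """Find models that contain metabolites of a given pathway."""
        if not self.pathway_exists(pathway_id):
            raise LookupFailure(f"unknown pathway {pathway_id!r}")
        rows = self._select(
            "SELECT DISTINCT s.modelId AS modelId "
            "FROM pathway_processes pp "
            "JOIN process_participants part ON part.processId = pp.processId "
            "JOIN MapSpeciesMolecularEntities msm "
            "  ON msm.molecularEntityId = part.molecularEntityId "
            "JOIN Species s ON s.id = msm.speciesId "
            "WHERE pp.pathwayId = ?",
            (pathway_id,),
        )
        return {r["modelId"] for r in rows}

    def query_flux_expressions_for_process(
        self, process_id: str
    ) -> dict[str, list[dict]]:
        """Find models containing different expressions of metabolic flux
        associated to the same process.

        Groups mapped reactions' kinetic laws by canonicalized MathML text
        and returns the groups only when at least two distinct expressions
        exist; algebraic equivalence is not attempted.
        """
        if not self.process_exists(process_id):
            raise LookupFailure(f"unknown process {process_id!r}")
        rows = self._select(
            "SELECT m.id AS modelId, m.sbmlId AS modelSbmlId, "
            "r.id AS reactionId, r.sbmlId AS reactionSbmlId, kl.math AS math "
            "FROM MapReactionsProcessEntities mrp "
            "JOIN Reaction r ON r.id = mrp.reactionId "
            "JOIN Model m ON m.id = r.modelId "
            "JOIN KineticLaw kl ON kl.reactionId = r.id "
            "WHERE mrp.processId = ? AND kl.math IS NOT NULL",
            (process_id,),
        )
        groups: dict[str, list[dict]] = {}
        for r in rows:
            math = canonicalize_mathml(r["math"]) or ""
            groups.setdefault(math, []).append(dict(r))
        if len(groups) < 2:
            return {}
        return groups

    def query_kinetic_models_for_process(
        self, pathway_id: str, process_id: str
    ) -> list[dict]:
        """Find kinetic models corresponding to a given process in a given
        pathway: mapped reactions with a kinetic law, empty if the process
        is not part of the pathway."""
        if not self.pathway_exists(pathway_id):
            raise LookupFailure(f"unknown pathway {pathway_id!r}")
        in_pathway = self._select(
            "SELECT 1 FROM pathway_processes WHERE pathwayId = ? AND processId = ?",
            (pathway_id, process_id),
        )
        if not in_pathway:
            return []
        rows = self._select(
            "SELECT m.id AS modelId, m.sbmlId AS modelSbmlId, "
            "r.id AS reactionId, r.sbmlId AS reactionSbmlId, kl.math AS math "
            "FROM MapReactionsProcessEntities mrp "
            "JOIN Reaction r ON r.id = mrp.reactionId "
            "JOIN Model m ON m.id = r.modelId "
            "JOIN KineticLaw kl ON kl.reactionId = r.id "
            "WHERE mrp.processId = ? AND kl.math IS NOT NULL "
            "ORDER BY m.sbmlId, r.sbmlId",
            (process_id,),
        )
        return [dict(r) for r in rows]

    def browse_models_by_go_term(self, go_id: str, labeling: Labeling) -> set[str]:
        """Models annotated to GO term *go_id* or any strict descendant.

        Descendants come from the precomputed NodeCodes labeling — no GO
        graph traversal happens at query time.
        """
        from .nodecodes import descendants_labeled

        if not self.go_term_exists(go_id):
            raise LookupFailure(f"unknown GO term {go_id!r}")
        wanted = descendants_labeled(labeling, go_id) | {go_id}
        placeholders = ",".join("?" for _ in wanted)
        rows = self._select(
            "SELECT DISTINCT i.modelId AS modelId "
            "FROM MapSbaseGO g JOIN SbaseIndex i ON i.sbaseId = g.sbaseId "
            f"WHERE g.goId IN ({placeholders})",
            tuple(wanted),
        )
        return {r["modelId"] for r in rows}
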