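"""Store persistence, cascade deletes, dimension cache, built-in queries."""

import pytest

from sblink import (
    Dag,
    IntegrityError,
    LookupFailure,
    Store,
    assign_nodecodes,
    extract_links_from_bundle,
    parse_sbml_document,
)
from sblink.store import CACHED_DIMENSION_TABLES

from conftest import TWO_SPECIES_DOC


def ingest(store: Store, doc: str, ds_name: str = "dsrc") -> str:
    ds = store.ensure_data_source(ds_name)
    bundle = parse_sbml_document(doc, ds, deterministic_ids=True)
    return store.persist_model_bundle(bundle, extract_links_from_bundle(bundle))


class TestPersistence:
    def test_row_counts_match_bundle(self, fresh_store):
        ds = fresh_store.ensure_data_source("d")
        bundle = parse_sbml_document(TWO_SPECIES_DOC, ds, deterministic_ids=True)
        fresh_store.persist_model_bundle(bundle, [])
        counts = fresh_store.table_counts()
        assert counts["Model"] == 1
        assert counts["Species"] == len(bundle.species) == 2
        assert counts["Reaction"] == len(bundle.reactions) == 1
        assert counts["ReactionSpecies"] == len(bundle.reaction_species) == 3
        assert counts["Compartment"] == 1

    def test_reingest_is_idempotent(self, fresh_store):
        ingest(fresh_store, TWO_SPECIES_DOC)
        before = fresh_store.table_counts()
        ingest(fresh_store, TWO_SPECIES_DOC)
        assert fresh_store.table_counts() == before

    def test_missing_compartment_reference_is_integrity_error(self, fresh_store):
        ds = fresh_store.ensure_data_source("d")
        bundle = parse_sbml_document(TWO_SPECIES_DOC, ds, deterministic_ids=True)
        bundle.species[0].compartment_id = "no-such-compartment"
        with pytest.raises(IntegrityError):
            fresh_store.persist_model_bundle(bundle, [])

    def test_sbase_row_backs_every_entity_row(self, fresh_store):
        ingest(fresh_store, TWO_SPECIES_DOC)
        assert fresh_store.orphan_rows() == []


class TestCascadeDelete:
    def test_single_model_leaves_all_model_tables_empty(self, fresh_store):
        model_id = ingest(fresh_store, TWO_SPECIES_DOC)
        removed = fresh_store.delete_model(model_id)
        assert removed > 0
        counts = fresh_store.table_counts()
        for table in ("Model", "Species", "Reaction", "ReactionSpecies",
                      "Compartment", "KineticLaw", "AnnotationLink"):
            assert counts[table] == 0, table

    def test_second_model_untouched(self, fresh_store):
        m1 = ingest(fresh_store, TWO_SPECIES_DOC)
        other = TWO_SPECIES_DOC.replace('id="M1"', 'id="M2"')
        ingest(fresh_store, other)
        fresh_store.delete_model(m1)
        counts = fresh_store.table_counts()
        assert counts["Model"] == 1 and counts["Species"] == 2

    def test_unknown_model_raises(self, fresh_store):
        with pytest.raises(LookupFailure):
            fresh_store.delete_model("nope")

    def test_mapping_rows_of_deleted_model_removed(self, scenario, tmp_path):
        # replay the scenario into a private store so deletion is isolated
        from conftest import build_populated_store

        store = Store.open(tmp_path / "del.sqlite")
        from sblink import build_crossref_index, load_pathway_source
        from sblink.mapping import build_annotation_tables, build_entity_mappings

        pstore = load_pathway_source(scenario["src"])
        store.persist_pathway_store(pstore)
        ds = store.ensure_data_source("scenario")
        ids = {}
        for sbml_id, doc in scenario["docs"].items():
            bundle = parse_sbml_document(doc, ds, deterministic_ids=True)
            store.persist_model_bundle(bundle, extract_links_from_bundle(bundle))
            ids[sbml_id] = bundle.model.id
        build_entity_mappings(store, build_crossref_index(pstore))
        build_annotation_tables(store)
        assert store.table_counts()["MapSpeciesMolecularEntities"] == 1
        store.delete_model(ids["MA"])
        counts = store.table_counts()
        assert counts["MapSpeciesMolecularEntities"] == 0
        assert counts["MapReactionECNumber"] == 0
        # MB's reaction-process row survives
        assert counts["MapReactionsProcessEntities"] == 1
        # pathway-side rows untouched
        assert counts["molecular_entities"] == 2
        assert store.orphan_rows() == []


class TestDimensionCache:
    def test_reaction_species_role_seeded_with_three_rows(self, fresh_store):
        rows = fresh_store.dimension_rows("ReactionSpeciesRole")
        assert sorted(rows.values()) == ["modifier", "product", "reactant"]

    def test_cache_rebuilds_on_dimension_write(self, fresh_store):
        fresh_store.add_dimension_row("RuleType", "parametric")
        assert "parametric" in fresh_store.dimension_rows("RuleType").values()

    def test_cache_hit_performs_zero_store_reads(self, fresh_store):
        fresh_store.dimension_rows("ReactionSpeciesRole")  # warm
        before = fresh_store.read_count
        for _ in range(5):
            fresh_store.dimension_rows("ReactionSpeciesRole")
        assert fresh_store.read_count == before

    def test_twelve_tables_configured(self):
        assert len(CACHED_DIMENSION_TABLES) == 12

    def test_qualifier_inserted_on_first_use(self, fresh_store):
        qid = fresh_store.qualifier_id("hasTaxon")
        assert fresh_store.qualifier_name(qid) == "hasTaxon"


class TestBuiltInQueries:
    def test_pathway_reactions_rows_with_resolved_roles(self, scenario):
        store = scenario["store"]
        rows = store.query_models_with_pathway_reactions("PW1")
        # MA.R1: 2 reactants + 1 product; MB.R9: 1 reactant -> 4 rows
        by_model = {}
        for r in rows:
            by_model.setdefault(r["modelSbmlId"], []).append(r)
        assert len(by_model["MA"]) == 3
        assert len(by_model["MB"]) == 1
        roles = sorted(r["role"] for r in by_model["MA"])
        assert roles == ["product", "reactant", "reactant"]
        assert any("(reactant)" in r["speciesNameWithRole"] for r in rows)

    def test_pathway_without_mapped_reactions_is_empty(self, scenario):
        assert scenario["store"].query_models_with_pathway_reactions("PW2") == []

    def test_unknown_pathway_raises(self, scenario):
        with pytest.raises(LookupFailure):
            scenario["store"].query_models_with_pathway_reactions("PW9")

    def test_two_models_mapped_to_same_process_both_appear(self, scenario):
        rows = scenario["store"].query_kinetic_models_for_process("PW1", "PR1")
        assert {r["modelSbmlId"] for r in rows} == {"MA", "MB"}

    def test_kinetic_models_process_not_in_pathway_is_empty(self, scenario):
        assert (
            scenario["store"].query_kinetic_models_for_process("PW1", "PR2") == []
        )

    def test_pathway_metabolites_only_mapped_model(self, scenario):
        got = scenario["store"].query_models_with_pathway_metabolites("PW1")
        assert got == {scenario["model_ids"]["MA"]}

    def test_pathway_metabolites_empty_for_unmapped_pathway(self, scenario):
        assert scenario["store"].query_models_with_pathway_metabolites("PW2") == set()

    def test_flux_expressions_two_distinct_laws_grouped(self, scenario):
        groups = scenario["store"].query_flux_expressions_for_process("PR1")
        assert len(groups) == 2
        models = {
            r["modelSbmlId"] for rows in groups.values() for r in rows
        }
        assert models == {"MA", "MB"}

    def test_flux_expressions_single_mapped_reaction_empty(self, scenario):
        assert scenario["store"].query_flux_expressions_for_process("PR2") == {}

    def test_queries_identical_with_cache_disabled(self, scenario):
        store = scenario["store"]
        with_cache = store.query_models_with_pathway_reactions("PW1")
        store.cache_enabled = False
        try:
            without_cache = store.query_models_with_pathway_reactions("PW1")
        finally:
            store.cache_enabled = True
        assert with_cache == without_cache


class TestBrowseByGoTerm:
    @pytest.fixture()
    def labeling(self, scenario):
        rows = scenario["store"].dump_table("go_term_parents")
        nodes = {r["id"] for r in scenario["store"].dump_table("go_terms")}
        edges = {(r["parentId"], r["goId"]) for r in rows}
        return assign_nodecodes(Dag(nodes=nodes, edges=edges))

    def test_annotation_to_descendant_included_at_ancestor(self, scenario, labeling):
        # MA annotates GO:0006096, a descendant of GO:0008150
        got = scenario["store"].browse_models_by_go_term("GO:0008150", labeling)
        assert scenario["model_ids"]["MA"] in got

    def test_annotation_to_term_itself_included(self, scenario, labeling):
        got = scenario["store"].browse_models_by_go_term("GO:0006096", labeling)
        assert scenario["model_ids"]["MA"] in got

    def test_sibling_branch_excluded(self, scenario, labeling):
        # MB annotates GO:0046323 (sibling branch of metabolic process)
        got = scenario["store"].browse_models_by_go_term("GO:0008152", labeling)
        assert scenario["model_ids"]["MB"] not in got
        assert scenario["model_ids"]["MA"] in got

    def test_unknown_go_term_raises(self, scenario, labeling):
        with pytest.raises(LookupFailure):
            scenario["store"].browse_models_by_go_term("GO:9999999", labeling)

    def test_matches_iterative_union_oracle(self, scenario, labeling):
        """browse(t) equals the union of direct lookups over descendants+t."""
        store = scenario["store"]
        rows = store.dump_table("MapSbaseGO")
        direct: dict[str, set] = {}
        for r in rows:
            kind = store.sbase_kind(r["sbaseId"])
            direct.setdefault(r["goId"], set()).add(kind[1])
        graph_rows = store.dump_table("go_term_parents")
        nodes = {r["id"] for r in store.dump_table("go_terms")}
        dag = Dag(
            nodes=nodes,
            edges={(r["parentId"], r["goId"]) for r in graph_rows},
        )
        from sblink import descendants_iterative

        for t in nodes:
            expected = set()
            desc, _ = descendants_iterative(dag, t)
            for d in desc | {t}:
                expected |= direct.get(d, set())
            assert store.browse_models_by_go_term(t, labeling) == expected
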