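"""Mapping/annotation table construction and ground-truth recovery."""

import pytest

from sblink import (
    Store,
    build_crossref_index,
    extract_links_from_bundle,
    load_pathway_source,
    parse_sbml_document,
    summarize_mappings,
)
from sblink.fixtures import expected_mapping_keys
from sblink.mapping import build_annotation_tables, build_entity_mappings

from conftest import annotation_block, bag, wrap_model


def make_store_with_source(tmp_path, src_writer):
    src = tmp_path / "src"
    src.mkdir()
    src_writer(src)
    store = Store.open(tmp_path / "m.sqlite")
    pstore = load_pathway_source(src)
    store.persist_pathway_store(pstore)
    return store, pstore


def minimal_source(src):
    (src / "molecular_entities.tsv").write_text(
        "id\tname\ttype\texternal_ids\n"
        "M7\tPEP\tcompound\tkegg.compound:C00074\n"
        "MD\tD-glucose\tcompound\tkegg.compound:C00031\n"
        "ML\tL-glucose\tcompound\tkegg.compound:C00031\n"
    )


def ingest_doc(store, doc):
    ds = store.ensure_data_source("d")
    bundle = parse_sbml_document(doc, ds, deterministic_ids=True)
    store.persist_model_bundle(bundle, extract_links_from_bundle(bundle))
    return bundle


def species_doc(urns_by_species: dict[str, list[str]]) -> str:
    species = []
    for sid, urns in urns_by_species.items():
        ann = annotation_block(
            f"m{sid}", f"<bqbiol:is>{bag(urns)}</bqbiol:is>"
        ) if urns else ""
        species.append(
            f'<species id="{sid}" metaid="m{sid}" compartment="c">{ann}</species>'
        )
    return wrap_model(
        '<listOfCompartments><compartment id="c"/></listOfCompartments>'
        "<listOfSpecies>" + "".join(species) + "</listOfSpecies>"
    )


class TestEntityMappings:
    def test_species_link_produces_row_with_qualifier(self, tmp_path):
        store, pstore = make_store_with_source(tmp_path, minimal_source)
        ingest_doc(store, species_doc({"S": ["urn:miriam:kegg.compound:C00074"]}))
        counts = build_entity_mappings(store, build_crossref_index(pstore))
        assert counts.species_molecular_entities == 1
        row = store.dump_table("MapSpeciesMolecularEntities")[0]
        assert row["molecularEntityId"] == "M7"
        assert store.qualifier_name(row["qualifierId"]) == "is"

    def test_unmatched_link_counted_not_rowed(self, tmp_path):
        store, pstore = make_store_with_source(tmp_path, minimal_source)
        ingest_doc(store, species_doc({"S": ["urn:miriam:kegg.compound:C99999"]}))
        counts = build_entity_mappings(store, build_crossref_index(pstore))
        assert counts.species_molecular_entities == 0
        assert counts.unmatched == 1
        assert store.dump_table("MapSpeciesMolecularEntities") == []

    def test_shared_accession_fans_out_to_both_conformations(self, tmp_path):
        """One glucose accession matching D- and L- entities -> two rows."""
        store, pstore = make_store_with_source(tmp_path, minimal_source)
        ingest_doc(store, species_doc({"S": ["urn:miriam:kegg.compound:C00031"]}))
        counts = build_entity_mappings(store, build_crossref_index(pstore))
        assert counts.species_molecular_entities == 2
        entities = {
            r["molecularEntityId"]
            for r in store.dump_table("MapSpeciesMolecularEntities")
        }
        assert entities == {"MD", "ML"}

    def test_mapping_never_creates_entities(self, tmp_path):
        """No-curation contract: entity-table row counts unchanged."""
        store, pstore = make_store_with_source(tmp_path, minimal_source)
        ingest_doc(store, species_doc({
            "S1": ["urn:miriam:kegg.compound:C00074"],
            "S2": ["urn:miriam:kegg.compound:C99999"],
        }))
        before = store.table_counts()
        build_entity_mappings(store, build_crossref_index(pstore))
        after = store.table_counts()
        for table in ("molecular_entities", "Species", "Model", "Reaction",
                      "processes", "pathways"):
            assert before[table] == after[table], table


class TestAnnotationTables:
    def _full_source(self, src):
        minimal_source(src)
        (src / "organism_groups.tsv").write_text(
            "id\tname\tncbi_taxonomy_ids\nOG1\ttryps\t5691\n"
        )
        (src / "go_terms.tsv").write_text(
            "go_id\tname\tparent_ids\nGO:0005829\tcytosol\t\n"
        )
        (src / "ec_numbers.tsv").write_text(
            "ec_number\tname\tnode_code\n5.3.1.9\tGPI\t\n"
        )

    def test_taxonomy_link_gives_model_organism_row(self, tmp_path):
        store, _ = make_store_with_source(tmp_path, self._full_source)
        doc = wrap_model(
            annotation_block(
                "mm", f"<bqbiol:is>{bag(['urn:miriam:taxonomy:5691'])}</bqbiol:is>"
            ),
            'id="M1" metaid="mm"',
        )
        ingest_doc(store, doc)
        counts = build_annotation_tables(store)
        assert counts.model_organism == 1
        row = store.dump_table("ModelOrganism")[0]
        assert row["NCBITaxonomyId"] == "5691"
        assert row["organismGroupId"] == "OG1"

    def test_ec_link_on_reaction(self, tmp_path):
        store, _ = make_store_with_source(tmp_path, self._full_source)
        doc = wrap_model(
            '<listOfReactions><reaction id="R" metaid="mr">'
            + annotation_block(
                "mr",
                "<bqbiol:isVersionOf>"
                + bag(["urn:miriam:ec-code:5.3.1.9"])
                + "</bqbiol:isVersionOf>",
            )
            + "</reaction></listOfReactions>"
        )
        ingest_doc(store, doc)
        counts = build_annotation_tables(store)
        assert counts.reaction_ec == 1
        row = store.dump_table("MapReactionECNumber")[0]
        assert row["ecNumber"] == "5.3.1.9"
        assert store.qualifier_name(row["qualifierId"]) == "isVersionOf"

    def test_compartment_go_link_annotates_compartment_sbase(self, tmp_path):
        store, _ = make_store_with_source(tmp_path, self._full_source)
        doc = wrap_model(
            '<listOfCompartments><compartment id="cyt" metaid="mc">'
            + annotation_block(
                "mc",
                f"<bqbiol:is>{bag(['urn:miriam:obo.go:GO%3A0005829'])}</bqbiol:is>",
            )
            + "</compartment></listOfCompartments>"
        )
        bundle = ingest_doc(store, doc)
        counts = build_annotation_tables(store)
        assert counts.sbase_go == 1
        row = store.dump_table("MapSbaseGO")[0]
        assert row["sbaseId"] == bundle.compartments[0].id
        assert row["goId"] == "GO:0005829"

    def test_go_link_to_unloaded_term_skipped(self, tmp_path):
        store, _ = make_store_with_source(tmp_path, self._full_source)
        doc = wrap_model(
            annotation_block(
                "mm",
                "<bqbiol:isVersionOf>"
                + bag(["urn:miriam:obo.go:GO%3A0099999"])
                + "</bqbiol:isVersionOf>",
            ),
            'id="M1" metaid="mm"',
        )
        ingest_doc(store, doc)
        counts = build_annotation_tables(store)
        assert counts.sbase_go == 0 and counts.skipped == 1
        assert store.orphan_rows() == []


class TestGroundTruthRecovery:
    def test_mapping_rows_equal_ledger_exactly(self, populated):
        """Precision = recall = 1.0 against the generator's ledger."""
        store = populated["store"]
        ledger = populated["corpus"]["ledger"]
        expected = expected_mapping_keys(ledger)

        got = {
            (r["modelSbmlId"], r["speciesSbmlId"], r["molecularEntityId"], r["qualifier"])
            for r in store.dump_table_with_names("MapSpeciesMolecularEntities")
        }
        assert got == expected["species_molecular_entities"]

        got = {
            (r["modelSbmlId"], r["reactionSbmlId"], r["processId"], r["qualifier"])
            for r in store.dump_table_with_names("MapReactionsProcessEntities")
        }
        assert got == expected["reactions_process_entities"]

        got = {
            (r["modelSbmlId"], r["modelSbmlId"], r["pathwayId"], r["qualifier"])
            for r in store.dump_table_with_names("MapModelsPathways")
        }
        assert got == expected["models_pathways"]

    def test_qualifier_conservation(self, populated):
        """Every mapping row's qualifier equals its source link's."""
        store = populated["store"]
        links = {
            (l["sbaseId"], l["namespace"], l["externalId"]): l["qualifier"]
            for l in store.annotation_links()
        }
        for row in store.dump_table("MapSpeciesMolecularEntities"):
            qualifier = store.qualifier_name(row["qualifierId"])
            assert any(
                q == qualifier
                for (sid, ns, _), q in links.items()
                if sid == row["speciesId"] and ns in ("kegg.compound", "obo.chebi")
            )

    def test_summary_matches_ledger_counts(self, populated):
        summary = summarize_mappings(populated["store"])
        ledger = populated["corpus"]["ledger"]
        exp = ledger["expected_mapping_rows"]
        assert summary.models_total == len(ledger["models"])
        assert summary.models_with_pathway_map == len(
            {r["model"] for r in exp["models_pathways"]}
        )
        assert summary.species_mapped == len(
            {(r["model"], r["element"]) for r in exp["species_molecular_entities"]}
        )
        assert summary.reactions_mapped == len(
            {(r["model"], r["element"]) for r in exp["reactions_process_entities"]}
        )

    def test_empty_store_summary_all_zero(self, fresh_store):
        summary = summarize_mappings(fresh_store)
        assert all(v == 0 for v in summary.as_dict().values())
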