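"""Shared fixtures: synthetic corpora, populated stores, hand-built models."""

from __future__ import annotations

from pathlib import Path

import pytest

from sblink import (
    Store,
    build_crossref_index,
    extract_links_from_bundle,
    load_pathway_source,
    parse_sbml_document,
)
from sblink.fixtures import (
    CorpusConfig,
    generate_model_corpus,
    generate_pathway_source,
)
from sblink.mapping import build_annotation_tables, build_entity_mappings

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL = "http://biomodels.net/biology-qualifiers/"
BQMODEL = "http://biomodels.net/model-qualifiers/"

CORPUS_SEED = 11


def wrap_model(body: str, model_attrs: str = 'id="M1"') -> str:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        f'<sbml xmlns="{SBML_NS}" level="2" version="4">'
        f"<model {model_attrs}>{body}</model></sbml>"
    )


#: Two species, one reaction (2 reactants, 1 product), one compartment.
TWO_SPECIES_DOC = wrap_model(
    "<listOfCompartments>"
    '<compartment id="cell" size="1"/>'
    "</listOfCompartments>"
    "<listOfSpecies>"
    '<species id="A" compartment="cell" initialConcentration="2"/>'
    '<species id="B" compartment="cell" initialAmount="1"/>'
    "</listOfSpecies>"
    "<listOfReactions>"
    '<reaction id="R1">'
    "<listOfReactants>"
    '<speciesReference species="A" stoichiometry="2"/>'
    '<speciesReference species="B"/>'
    "</listOfReactants>"
    "<listOfProducts>"
    '<speciesReference species="A"/>'
    "</listOfProducts>"
    "</reaction>"
    "</listOfReactions>"
)


def annotation_block(meta_id: str, qualifier_xml: str) -> str:
    return (
        "<annotation>"
        f'<rdf:RDF xmlns:rdf="{RDF}" xmlns:bqbiol="{BQBIOL}" '
        f'xmlns:bqmodel="{BQMODEL}">'
        f'<rdf:Description rdf:about="#{meta_id}">'
        f"{qualifier_xml}"
        "</rdf:Description></rdf:RDF></annotation>"
    )


def bag(urns: list[str]) -> str:
    items = "".join(f'<rdf:li rdf:resource="{u}"/>' for u in urns)
    return f"<rdf:Bag>{items}</rdf:Bag>"


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """10-model synthetic corpus + aligned pathway source, fixed seed."""
    root = tmp_path_factory.mktemp("corpus")
    config = CorpusConfig(n_models=10)
    docs, ledger = generate_model_corpus(config, CORPUS_SEED, root / "models")
    generate_pathway_source(ledger, CORPUS_SEED, root / "pathway_source")
    return {"root": root, "docs": docs, "ledger": ledger}


def build_populated_store(corpus, db_path) -> tuple[Store, dict]:
    store = Store.open(db_path)
    pstore = load_pathway_source(corpus["root"] / "pathway_source")
    store.persist_pathway_store(pstore)
    ds = store.ensure_data_source("synthetic-corpus")
    for text in corpus["docs"].values():
        bundle = parse_sbml_document(text, ds, deterministic_ids=True)
        store.persist_model_bundle(bundle, extract_links_from_bundle(bundle))
    index = build_crossref_index(pstore)
    mcounts = build_entity_mappings(store, index)
    acounts = build_annotation_tables(store)
    return store, {
        "pstore": pstore,
        "mapping_counts": mcounts,
        "annotation_counts": acounts,
    }


@pytest.fixture(scope="session")
def populated(corpus, tmp_path_factory):
    """Fully ingested + mapped store over the session corpus."""
    db = tmp_path_factory.mktemp("db") / "store.sqlite"
    store, extras = build_populated_store(corpus, db)
    return {"store": store, "corpus": corpus, **extras}


@pytest.fixture()
def fresh_store(tmp_path) -> Store:
    return Store.open(tmp_path / "fresh.sqlite")


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Hand-built two-model scenario over one pathway for query tests.

    Pathway PW1 contains process PR1 (KEGG reaction R00771) whose
    participants are ME1/ME2.  Model MA's reaction R1 (2 reactants + 1
    product, mass-action law kA) and model MB's reaction R9 (different law)
    both annotate to R00771; MA's species Apep annotates to C00074 (ME1).
    """
    root = tmp_path_factory.mktemp("scenario")
    src = root / "pathway_source"
    src.mkdir()
    (src / "molecular_entities.tsv").write_text(
        "id\tname\ttype\texternal_ids\n"
        "ME1\tPEP\tcompound\tkegg.compound:C00074\n"
        "ME2\tpyruvate\tcompound\tkegg.compound:C00022\n"
    )
    (src / "processes.tsv").write_text(
        "id\tname\tec_numbers\texternal_ids\n"
        "PR1\tglycolytic step\t5.3.1.9\tkegg.reaction:R00771\n"
        "PR2\tother step\t\tkegg.reaction:R99999\n"
    )
    (src / "process_participants.tsv").write_text(
        "process_id\tmolecular_entity_id\trole\n"
        "PR1\tME1\tsubstrate\nPR1\tME2\tproduct\n"
    )
    (src / "organism_groups.tsv").write_text(
        "id\tname\tncbi_taxonomy_ids\nOG1\ttrypanosomes\t5691\n"
    )
    (src / "pathways.tsv").write_text(
        "id\tname\torganism_group_id\texternal_ids\n"
        "PW1\tglycolysis\tOG1\tkegg.pathway:tbr00010\n"
        "PW2\tempty pathway\t\tkegg.pathway:tbr99999\n"
    )
    (src / "pathway_processes.tsv").write_text(
        "pathway_id\tprocess_id\nPW1\tPR1\n"
    )
    (src / "go_terms.tsv").write_text(
        "go_id\tname\tparent_ids\n"
        "GO:0008150\tbiological_process\t\n"
        "GO:0008152\tmetabolic process\tGO:0008150\n"
        "GO:0006096\tglycolytic process\tGO:0008152\n"
        "GO:0046323\tglucose import\tGO:0008150\n"
        "GO:0005829\tcytosol\t\n"
    )
    (src / "ec_numbers.tsv").write_text(
        "ec_number\tname\tnode_code\n5.3.1.9\tGPI\t\n"
    )

    def kinetic(body: str) -> str:
        return (
            "<kineticLaw>"
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            f"{body}</math></kineticLaw>"
        )

    model_a = wrap_model(
        annotation_block(
            "mA",
            f"<bqbiol:is>{bag(['urn:miriam:kegg.pathway:tbr00010'])}</bqbiol:is>"
            f"<bqbiol:is>{bag(['urn:miriam:taxonomy:5691'])}</bqbiol:is>"
            "<bqbiol:isVersionOf>"
            + bag(["urn:miriam:obo.go:GO%3A0006096"])
            + "</bqbiol:isVersionOf>",
        )
        + "<listOfCompartments>"
        + '<compartment id="cytosol" metaid="mAc" size="1">'
        + annotation_block(
            "mAc", f"<bqbiol:is>{bag(['urn:miriam:obo.go:GO%3A0005829'])}</bqbiol:is>"
        )
        + "</compartment></listOfCompartments>"
        + "<listOfSpecies>"
        + '<species id="Apep" metaid="mAs" compartment="cytosol">'
        + annotation_block(
            "mAs", f"<bqbiol:is>{bag(['urn:miriam:kegg.compound:C00074'])}</bqbiol:is>"
        )
        + "</species>"
        + '<species id="Apyr" compartment="cytosol"/>'
        + '<species id="Aatp" compartment="cytosol"/>'
        + "</listOfSpecies>"
        + "<listOfReactions>"
        + '<reaction id="R1" metaid="mAr">'
        + annotation_block(
            "mAr",
            f"<bqbiol:is>{bag(['urn:miriam:kegg.reaction:R00771'])}</bqbiol:is>"
            "<bqbiol:isVersionOf>"
            + bag(["urn:miriam:ec-code:5.3.1.9"])
            + "</bqbiol:isVersionOf>",
        )
        + "<listOfReactants>"
        + '<speciesReference species="Apep"/>'
        + '<speciesReference species="Aatp"/>'
        + "</listOfReactants>"
        + '<listOfProducts><speciesReference species="Apyr"/></listOfProducts>'
        + kinetic("<apply><times/><ci>kA</ci><ci>Apep</ci></apply>")
        + "</reaction>"
        + "</listOfReactions>",
        'id="MA" metaid="mA"',
    )
    model_b = wrap_model(
        annotation_block(
            "mB",
            "<bqbiol:isVersionOf>"
            + bag(["urn:miriam:obo.go:GO%3A0046323"])
            + "</bqbiol:isVersionOf>",
        )
        + "<listOfCompartments>"
        + '<compartment id="cytosol" size="1"/></listOfCompartments>'
        + "<listOfSpecies>"
        + '<species id="Bpep" compartment="cytosol"/></listOfSpecies>'
        + "<listOfReactions>"
        + '<reaction id="R9" metaid="mBr">'
        + annotation_block(
            "mBr",
            f"<bqbiol:is>{bag(['urn:miriam:kegg.reaction:R00771'])}</bqbiol:is>",
        )
        + '<listOfReactants><speciesReference species="Bpep"/></listOfReactants>'
        + kinetic(
            "<apply><divide/><ci>Vmax</ci>"
            "<apply><plus/><ci>Km</ci><ci>Bpep</ci></apply></apply>"
        )
        + "</reaction></listOfReactions>",
        'id="MB" metaid="mB"',
    )

    db = root / "scenario.sqlite"
    store = Store.open(db)
    pstore = load_pathway_source(src)
    store.persist_pathway_store(pstore)
    ds = store.ensure_data_source("scenario")
    model_ids = {}
    for text in (model_a, model_b):
        bundle = parse_sbml_document(text, ds, deterministic_ids=True)
        store.persist_model_bundle(bundle, extract_links_from_bundle(bundle))
        model_ids[bundle.model.sbml_id] = bundle.model.id
    index = build_crossref_index(pstore)
    mcounts = build_entity_mappings(store, index)
    acounts = build_annotation_tables(store)
    return {
        "store": store,
        "pstore": pstore,
        "model_ids": model_ids,
        "mapping_counts": mcounts,
        "annotation_counts": acounts,
        "docs": {"MA": model_a, "MB": model_b},
        "src": src,
        "root": root,
    }
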