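"""Cross-source mapping and annotation tables.

Builds the three mapping tables (species <-> molecular entities,
reactions <-> process entities, models <-> pathways) and the three
annotation tables (model organisms, GO terms on any entity, EC numbers on
reactions) from extracted annotation links plus the pathway cross-reference
index.  Mapping is purely mechanical — it never curates: no pathway-side or
model-side entity is ever created, links without an index match are merely
counted as unmatched, and every produced row carries the qualifier of the
link it came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .pathway import PathwayStore
from .store import Store

logger = logging.getLogger(__name__)

#: Namespaces that feed each mapping table; species match on compound
#: accessions first (KEGG) and ChEBI second, both producing rows.
SPECIES_NAMESPACES = ("kegg.compound", "obo.chebi")
REACTION_NAMESPACE = "kegg.reaction"
PATHWAY_NAMESPACE = "kegg.pathway"
TAXONOMY_NAMESPACE = "taxonomy"
GO_NAMESPACE = "obo.go"
EC_NAMESPACE = "ec-code"


@dataclass
class MappingCounts:
    species_molecular_entities: int = 0
    reactions_process_entities: int = 0
    models_pathways: int = 0
    unmatched: int = 0
    unmatched_links: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "species_molecular_entities": self.species_molecular_entities,
            "reactions_process_entities": self.reactions_process_entities,
            "models_pathways": self.models_pathways,
            "unmatched": self.unmatched,
        }


@dataclass
class AnnotationCounts:
    model_organism: int = 0
    sbase_go: int = 0
    reaction_ec: int = 0
    skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "model_organism": self.model_organism,
            "sbase_go": self.sbase_go,
            "reaction_ec": self.reaction_ec,
            "skipped": self.skipped,
        }


def build_entity_mappings(
    store: Store,
    index: dict[tuple[str, str], list[tuple[str, str]]],
) -> MappingCounts:
    """Populate the three mapping tables from persisted annotation links.

    Fan-out is allowed in both directions: one link matching several
    entities yields several rows (one compound accession shared by two
    optical conformations), and one entity matched by several links on the
    same subject yields several rows.  Duplicate rows collapse on the full
    (entity, target, qualifier) key.
    """
    counts = MappingCounts()
    for link in store.annotation_links():
        ns, xid = link["namespace"], link["externalId"]
        kind = link["kind"]
        qid = store.qualifier_id(link["qualifier"])
        matched = False
        if kind == "species" and ns in SPECIES_NAMESPACES:
            for tkind, target in index.get((ns, xid), []):
                if tkind == "molecular_entity":
                    if store.add_map_species_molecular_entity(
                        link["sbaseId"], target, qid
                    ):
                        counts.species_molecular_entities += 1
                    matched = True
        elif kind == "reaction" and ns == REACTION_NAMESPACE:
            for tkind, target in index.get((ns, xid), []):
                if tkind == "process":
                    if store.add_map_reaction_process(link["sbaseId"], target, qid):
                        counts.reactions_process_entities += 1
                    matched = True
        elif kind == "model" and ns == PATHWAY_NAMESPACE:
            for tkind, target in index.get((ns, xid), []):
                if tkind == "pathway":
                    og = store.pathway_organism_group(target)
                    if store.add_map_model_pathway(link["sbaseId"], target, qid, og):
                        counts.models_pathways += 1
                    matched = True
        else:
            continue  # namespace not mapped for this entity kind
        if not matched:
            counts.unmatched += 1
            counts.unmatched_links.append((kind, ns, xid))
            logger.info("unmatched %s link %s:%s", kind, ns, xid)
    return counts


def build_annotation_tables(store: Store) -> AnnotationCounts:
    """Populate ModelOrganism, MapSbaseGO and MapReactionECNumber.

    GO links whose term is absent from the loaded go_terms, and EC links
    whose number is absent from ec_numbers, are skipped with a log line so
    referential integrity holds.
    """
    counts = AnnotationCounts()
    for link in store.annotation_links():
        ns, xid = link["namespace"], link["externalId"]
        kind = link["kind"]
        qid = store.qualifier_id(link["qualifier"])
        if ns == TAXONOMY_NAMESPACE and kind == "model":
            og = store.organism_group_of_taxon(xid)
            if store.add_model_organism(link["sbaseId"], og, xid, qid):
                counts.model_organism += 1
        elif ns == GO_NAMESPACE:
            if not store.go_term_exists(xid):
                counts.skipped += 1
                logger.info("skipping GO link to unloaded term %s", xid)
                continue
            if store.add_map_sbase_go(link["sbaseId"], xid, qid):
                counts.sbase_go += 1
        elif ns == EC_NAMESPACE and kind == "reaction":
            if not store.ec_number_exists(xid):
                counts.skipped += 1
                logger.info("skipping EC link to unloaded number %s", xid)
                continue
            if store.add_map_reaction_ec(link["sbaseId"], xid, qid):
                counts.reaction_ec += 1
    return counts


def build_all_mappings(
    store: Store, pstore: PathwayStore
) -> tuple[MappingCounts, AnnotationCounts]:
    """Convenience: cross-reference index + both build passes."""
    from .pathway import build_crossref_index

    index = build_crossref_index(pstore)
    return build_entity_mappings(store, index), build_annotation_tables(store)


@dataclass
class MappingSummary:
    models_total: int
    models_with_pathway_map: int
    models_with_go_annotation: int
    reactions_total: int
    reactions_mapped: int
    species_total: int
    species_mapped: int
    distinct_pathways_hit: int
    distinct_processes_hit: int
    distinct_molecular_entities_hit: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_mappings(store: Store) -> MappingSummary:
    """Distinct-count summary of the mapping state, deterministic."""
    return MappingSummary(**store.mapping_summary_counts())


def export_mapping_tables(store: Store, directory) -> None:
    """Dump the six mapping/annotation tables as TSV."""
    import csv
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = (
        "MapSpeciesMolecularEntities", "MapReactionsProcessEntities",
        "MapModelsPathways", "ModelOrganism", "MapSbaseGO",
        "MapReactionECNumber",
    )
    for table in tables:
        rows = store.dump_table(table)
        with open(directory / f"{table}.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            if rows:
                writer.writerow(rows[0].keys())
                writer.writerows(tuple(r) for r in rows)
            else:
                writer.writerow([])
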