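"""Pathway-side store: KEGG-like molecular entities, processes, pathways.

Model-side and pathway-side data are kept loosely coupled — separate
containers joined only through explicit mapping tables — so the pathway
store has its own flat-file dialect: TSV tables with header rows, external
ids serialized ``namespace:id`` and semicolon-separated.  GO terms may
alternatively be read from a minimal OBO file (id, name, is_a).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import IntegrityError

FILES = (
    "molecular_entities.tsv",
    "processes.tsv",
    "process_participants.tsv",
    "pathways.tsv",
    "pathway_processes.tsv",
    "organism_groups.tsv",
    "go_terms.tsv",
    "ec_numbers.tsv",
)

#: Roles a molecular entity can play in a process.
PROCESS_ENTITY_ROLES = ("substrate", "product", "cofactor", "inhibitor", "activator")


def _split_xrefs(cell) -> set[tuple[str, str]]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return set()
    out = set()
    for token in str(cell).split(";"):
        token = token.strip()
        if not token:
            continue
        ns, _, xid = token.partition(":")
        out.add((ns.lower(), xid))
    return out


def _split_list(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [t.strip() for t in str(cell).split(";") if t.strip()]


@dataclass
class MolecularEntity:
    id: str
    name: str
    type: str = "compound"
    external_ids: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class ProcessEntity:
    id: str
    name: str
    ec_numbers: set[str] = field(default_factory=set)
    external_ids: set[tuple[str, str]] = field(default_factory=set)
    participants: list[tuple[str, str]] = field(default_factory=list)  # (me id, role)


@dataclass
class Pathway:
    id: str
    name: str
    organism_group_id: str | None = None
    process_ids: list[str] = field(default_factory=list)
    external_ids: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class GoTerm:
    go_id: str
    name: str
    parent_ids: list[str] = field(default_factory=list)  # is_a


@dataclass
class EcNumberNode:
    ec_number: str
    name: str
    node_code: str | None = None


@dataclass
class OrganismGroup:
    id: str
    name: str
    ncbi_taxonomy_ids: set[str] = field(default_factory=set)


@dataclass
class PathwayStore:
    molecular_entities: dict[str, MolecularEntity] = field(default_factory=dict)
    processes: dict[str, ProcessEntity] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)
    go_terms: dict[str, GoTerm] = field(default_factory=dict)
    ec_numbers: dict[str, EcNumberNode] = field(default_factory=dict)
    organism_groups: dict[str, OrganismGroup] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "molecular_entities": len(self.molecular_entities),
            "processes": len(self.processes),
            "pathways": len(self.pathways),
            "go_terms": len(self.go_terms),
            "ec_numbers": len(self.ec_numbers),
            "organism_groups": len(self.organism_groups),
        }

    def go_graph(self) -> nx.DiGraph:
        """GO is_a graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.go_terms)
        for term in self.go_terms.values():
            for parent in term.parent_ids:
                g.add_edge(parent, term.go_id)
        return g

    def organism_group_of_taxon(self, taxonomy_id: str) -> str | None:
        for group in self.organism_groups.values():
            if taxonomy_id in group.ncbi_taxonomy_ids:
                return group.id
        return None


def _read(directory: Path, name: str) -> pd.DataFrame | None:
    path = directory / name
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df


def load_pathway_source(directory: str | Path) -> PathwayStore:
    """Load a pathway source from its TSV directory.

    Enforces referential integrity: duplicate primary ids and dangling
    process/pathway/participant references raise :class:`IntegrityError`
    naming the offender.  Missing files are treated as empty tables.
    """
    directory = Path(directory)
    store = PathwayStore()

    df = _read(directory, "molecular_entities.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.id in store.molecular_entities:
                raise IntegrityError(f"duplicate molecular entity id {row.id!r}")
            store.molecular_entities[row.id] = MolecularEntity(
                id=row.id,
                name=row.name,
                type=getattr(row, "type", "compound") or "compound",
                external_ids=_split_xrefs(getattr(row, "external_ids", "")),
            )

    df = _read(directory, "processes.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.id in store.processes:
                raise IntegrityError(f"duplicate process id {row.id!r}")
            store.processes[row.id] = ProcessEntity(
                id=row.id,
                name=row.name,
                ec_numbers=set(_split_list(getattr(row, "ec_numbers", ""))),
                external_ids=_split_xrefs(getattr(row, "external_ids", "")),
            )

    df = _read(directory, "process_participants.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            proc = store.processes.get(row.process_id)
            if proc is None:
                raise IntegrityError(
                    f"participant references missing process {row.process_id!r}"
                )
            if row.molecular_entity_id not in store.molecular_entities:
                raise IntegrityError(
                    "participant references missing molecular entity "
                    f"{row.molecular_entity_id!r}"
                )
            proc.participants.append((row.molecular_entity_id, row.role))

    df = _read(directory, "organism_groups.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.id in store.organism_groups:
                raise IntegrityError(f"duplicate organism group id {row.id!r}")
            store.organism_groups[row.id] = OrganismGroup(
                id=row.id,
                name=row.name,
                ncbi_taxonomy_ids=set(_split_list(getattr(row, "ncbi_taxonomy_ids", ""))),
            )

    df = _read(directory, "pathways.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.id in store.pathways:
                raise IntegrityError(f"duplicate pathway id {row.id!r}")
            og = getattr(row, "organism_group_id", "") or None
            if og is not None and og not in store.organism_groups:
                raise IntegrityError(
                    f"pathway {row.id!r} references missing organism group {og!r}"
                )
            store.pathways[row.id] = Pathway(
                id=row.id,
                name=row.name,
                organism_group_id=og,
                external_ids=_split_xrefs(getattr(row, "external_ids", "")),
            )

    df = _read(directory, "pathway_processes.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            pw = store.pathways.get(row.pathway_id)
            if pw is None:
                raise IntegrityError(
                    f"pathway_processes references missing pathway {row.pathway_id!r}"
                )
            if row.process_id not in store.processes:
                raise IntegrityError(
                    f"pathway {row.pathway_id!r} references missing process "
                    f"{row.process_id!r}"
                )
            pw.process_ids.append(row.process_id)

    df = _read(directory, "go_terms.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.go_id in store.go_terms:
                raise IntegrityError(f"duplicate GO term {row.go_id!r}")
            store.go_terms[row.go_id] = GoTerm(
                go_id=row.go_id,
                name=row.name,
                parent_ids=_split_list(getattr(row, "parent_ids", "")),
            )
        graph = store.go_graph()
        if not nx.is_directed_acyclic_graph(graph):
            raise IntegrityError("GO term graph contains a cycle")

    df = _read(directory, "ec_numbers.tsv")
    if df is not None:
        for row in df.itertuples(index=False):
            if row.ec_number in store.ec_numbers:
                raise IntegrityError(f"duplicate EC number {row.ec_number!r}")
            store.ec_numbers[row.ec_number] = EcNumberNode(
                ec_number=row.ec_number,
                name=row.name,
                node_code=getattr(row, "node_code", "") or None,
            )

    return store


def load_go_from_obo(path: str | Path) -> dict[str, GoTerm]:
    """Read GO terms from a minimal OBO file (id, name, is_a only)."""
    import obonet

    graph = obonet.read_obo(str(path))
    terms: dict[str, GoTerm] = {}
    for node, data in graph.nodes(data=True):
        parents = [
            p if isinstance(p, str) else p[0] for p in data.get("is_a", [])
        ]
        terms[node] = GoTerm(
            go_id=node, name=data.get("name", node), parent_ids=parents
        )
    return terms


def build_crossref_index(
    store: PathwayStore,
) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """Index (namespace, external id) -> [(entity kind, entity id), ...].

    One key may map to several entities (e.g. two optical conformations of a
    metabolite sharing one compound accession) and one entity may hold
    several keys; the index is therefore many-to-many.
    """
    index: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for kind, entities in (
        ("molecular_entity", store.molecular_entities),
        ("process", store.processes),
        ("pathway", store.pathways),
    ):
        for entity in entities.values():
            for key in entity.external_ids:
                index.setdefault(key, []).append((kind, entity.id))
    return index
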