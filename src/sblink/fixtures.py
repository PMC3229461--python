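"""Synthetic test corpora with machine-readable ground truth.

Generates three kinds of inputs, all deterministic for a fixed seed:

* BioModels-style SBML Level 2 documents whose annotation blocks plant
  MIRIAM links (KEGG pathway/reaction/compound, GO, NCBI taxonomy, EC,
  PubMed) with configurable per-entity coverage fractions;
* an aligned pathway source (the TSV dialect) whose external ids coincide
  with the planted links, so the exact set of expected mapping rows is
  decidable from the emitted ledger alone;
* random ranked DAGs for exercising the labeling scheme.

A configurable fraction of planted links references accessions absent from
the pathway source, to exercise unmatched-link paths.  Per-model planted
link counts use the floor rule: ``floor(coverage * n_entities)``.

The generated kinetics are deliberately not biologically meaningful; the
corpus emulates the *structure* of curated model repositories (entity
counts, annotation grammar, coverage patterns), not their chemistry.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .nodecodes import Dag

_SBML_NS = "http://www.sbml.org/sbml/level2/version4"
_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_BQBIOL = "http://biomodels.net/biology-qualifiers/"
_BQMODEL = "http://biomodels.net/model-qualifiers/"


@dataclass
class CorpusConfig:
    """Shape of a synthetic corpus; fractions are per-entity coverages."""

    n_models: int = 10
    species_per_model: int = 5
    reactions_per_model: int = 4
    kegg_compound_coverage: float = 0.6
    kegg_reaction_coverage: float = 0.5
    ec_coverage: float = 0.25
    model_pathway_fraction: float = 0.6
    model_taxonomy_fraction: float = 0.9
    model_go_fraction: float = 0.8
    compartment_go_fraction: float = 0.5
    #: fraction of planted links whose accession is absent from the source
    unmatched_fraction: float = 0.0
    #: weights for the qualifier used on compound/reaction links
    qualifier_mix: dict = field(
        default_factory=lambda: {"is": 0.7, "isVersionOf": 0.3}
    )

    def validate(self) -> None:
        for name in (
            "kegg_compound_coverage", "kegg_reaction_coverage", "ec_coverage",
            "model_pathway_fraction", "model_taxonomy_fraction",
            "model_go_fraction", "compartment_go_fraction",
            "unmatched_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_models < 0 or self.species_per_model < 0 or self.reactions_per_model < 0:
            raise ValidationError("counts must be non-negative")
        if not self.qualifier_mix or any(w < 0 for w in self.qualifier_mix.values()):
            raise ValidationError("qualifier_mix must be non-empty, non-negative")


#: A compact GO-like hierarchy used by every synthetic corpus: a
#: biological-process branch and a cellular-component branch.
GO_TERMS: list[tuple[str, str, list[str]]] = [
    ("GO:0008150", "biological_process", []),
    ("GO:0008152", "metabolic process", ["GO:0008150"]),
    ("GO:0044237", "cellular metabolic process", ["GO:0008152"]),
    ("GO:0006096", "glycolytic process", ["GO:0044237"]),
    ("GO:0046323", "glucose import", ["GO:0008150"]),
    ("GO:0005575", "cellular_component", []),
    ("GO:0005622", "intracellular", ["GO:0005575"]),
    ("GO:0005829", "cytosol", ["GO:0005622"]),
]

_BP_ROOT = "GO:0008150"


def _weighted_choice(rng: random.Random, mix: dict) -> str:
    names = sorted(mix)
    weights = [mix[n] for n in names]
    return rng.choices(names, weights=weights, k=1)[0]


def _annotation(meta_id: str, items: list[tuple[str, str, str]]) -> str:
    """RDF annotation block: items are (qualifier element, family, urn)."""
    if not items:
        return ""
    by_qual: dict[tuple[str, str], list[str]] = {}
    for qual, family, urn in items:
        by_qual.setdefault((qual, family), []).append(urn)
    parts = [
        "<annotation>",
        f'<rdf:RDF xmlns:rdf="{_RDF_NS}" xmlns:bqbiol="{_BQBIOL}" '
        f'xmlns:bqmodel="{_BQMODEL}">',
        f'<rdf:Description rdf:about="#{meta_id}">',
    ]
    for (qual, family), urns in by_qual.items():
        prefix = "bqmodel" if family == "model" else "bqbiol"
        parts.append(f"<{prefix}:{qual}><rdf:Bag>")
        for urn in urns:
            parts.append(f'<rdf:li rdf:resource="{urn}"/>')
        parts.append(f"</rdf:Bag></{prefix}:{qual}>")
    parts.append("</rdf:Description></rdf:RDF></annotation>")
    return "".join(parts)


def generate_model_corpus(
    config: CorpusConfig, seed: int, out_dir: str | Path | None = None
) -> tuple[dict[str, str], dict]:
    """Generate SBML documents plus the ground-truth ledger.

    Returns ``(documents, ledger)`` where *documents* maps filename to XML
    text.  When *out_dir* is given the documents and ``ledger.json`` are
    also written there.  Same (config, seed) yields byte-identical output.
    """
    config.validate()
    rng = random.Random(seed)

    n_compounds = max(1, config.n_models * config.species_per_model // 2)
    n_kegg_reactions = max(1, config.n_models * config.reactions_per_model // 2)
    compounds = [f"C{i:05d}" for i in range(1, n_compounds + 1)]
    kegg_reactions = [f"R{i:05d}" for i in range(1, n_kegg_reactions + 1)]
    pathways = [f"path{i:05d}" for i in range(1, max(2, config.n_models // 3) + 1)]
    taxa = ["9606", "4932", "5691", "10090"]
    ec_numbers = ["5.3.1.9", "2.7.1.1", "1.1.1.1", "4.1.2.13"]

    ledger: dict = {
        "seed": seed,
        "config": dict(config.__dict__),
        "universe": {
            "compounds": compounds,
            "kegg_reactions": kegg_reactions,
            "pathways": pathways,
            "taxa": taxa,
            "ec_numbers": ec_numbers,
            "go_terms": [
                {"go_id": g, "name": n, "parent_ids": p} for g, n, p in GO_TERMS
            ],
        },
        "models": [],
        "planted_links": [],
        "expected_mapping_rows": {
            "species_molecular_entities": [],
            "reactions_process_entities": [],
            "models_pathways": [],
            "model_organism": [],
            "sbase_go": [],
            "reaction_ec": [],
        },
    }

    def plant(model, kind, element, qual, family, namespace, ext_id, matched):
        urn_id = ext_id.replace(":", "%3A")
        urn = f"urn:miriam:{namespace}:{urn_id}"
        ledger["planted_links"].append(
            {
                "model": model, "kind": kind, "element": element,
                "qualifier": qual, "family": family, "namespace": namespace,
                "external_id": ext_id, "matched": matched,
            }
        )
        return (qual, family, urn)

    documents: dict[str, str] = {}
    go_biology_terms = [g for g, _, _ in GO_TERMS[:5]]
    go_component_terms = ["GO:0005829", "GO:0005622"]

    for mi in range(config.n_models):
        model_id = f"synthModel{mi:03d}"
        compartment_id = "cytoplasm"
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<sbml xmlns="{_SBML_NS}" level="2" version="4">',
        ]
        model_counts = {
            "species": config.species_per_model,
            "reactions": config.reactions_per_model,
            "compartments": 1,
        }

        # model-level links
        model_items: list[tuple[str, str, str]] = []
        if rng.random() < config.model_pathway_fraction:
            unmatched = rng.random() < config.unmatched_fraction
            pw = "pathZZZZZ" if unmatched else rng.choice(pathways)
            model_items.append(
                plant(model_id, "model", model_id, "is", "biology",
                      "kegg.pathway", pw, not unmatched)
            )
            if not unmatched:
                ledger["expected_mapping_rows"]["models_pathways"].append(
                    {"model": model_id, "pathway": pw, "qualifier": "is"}
                )
        if rng.random() < config.model_taxonomy_fraction:
            taxon = rng.choice(taxa)
            model_items.append(
                plant(model_id, "model", model_id, "is", "biology",
                      "taxonomy", taxon, True)
            )
            ledger["expected_mapping_rows"]["model_organism"].append(
                {"model": model_id, "taxon": taxon, "qualifier": "is"}
            )
        if rng.random() < config.model_go_fraction:
            term = rng.choice(go_biology_terms)
            model_items.append(
                plant(model_id, "model", model_id, "isVersionOf", "biology",
                      "obo.go", term, True)
            )
            ledger["expected_mapping_rows"]["sbase_go"].append(
                {"model": model_id, "element": model_id, "kind": "model",
                 "go_id": term, "qualifier": "isVersionOf"}
            )
        model_items.append(
            plant(model_id, "model", model_id, "isDescribedBy", "model",
                  "pubmed", str(10000000 + mi), True)
        )

        meta = f"meta_{model_id}"
        ann = _annotation(meta, model_items)
        lines.append(f'<model id="{model_id}" metaid="{meta}">{ann}')

        # compartment, possibly GO-annotated
        comp_items = []
        if rng.random() < config.compartment_go_fraction:
            term = rng.choice(go_component_terms)
            comp_items.append(
                plant(model_id, "compartment", compartment_id, "is", "biology",
                      "obo.go", term, True)
            )
            ledger["expected_mapping_rows"]["sbase_go"].append(
                {"model": model_id, "element": compartment_id,
                 "kind": "compartment", "go_id": term, "qualifier": "is"}
            )
        comp_meta = f"meta_{model_id}_c"
        lines.append("<listOfCompartments>")
        lines.append(
            f'<compartment id="{compartment_id}" metaid="{comp_meta}" size="1">'
            f"{_annotation(comp_meta, comp_items)}</compartment>"
        )
        lines.append("</listOfCompartments>")

        # species with compound links: floor(coverage * n) of them annotated
        n_sp_links = math.floor(
            config.kegg_compound_coverage * config.species_per_model
        )
        lines.append("<listOfSpecies>")
        for si in range(config.species_per_model):
            sp_id = f"S{si}"
            items = []
            if si < n_sp_links:
                unmatched = rng.random() < config.unmatched_fraction
                cid = "CZZZZZ" if unmatched else rng.choice(compounds)
                qual = _weighted_choice(rng, config.qualifier_mix)
                items.append(
                    plant(model_id, "species", sp_id, qual, "biology",
                          "kegg.compound", cid, not unmatched)
                )
                if not unmatched:
                    ledger["expected_mapping_rows"][
                        "species_molecular_entities"
                    ].append(
                        {"model": model_id, "element": sp_id,
                         "compound": cid, "qualifier": qual}
                    )
            sp_meta = f"meta_{model_id}_{sp_id}"
            lines.append(
                f'<species id="{sp_id}" metaid="{sp_meta}" '
                f'compartment="{compartment_id}" initialConcentration="1">'
                f"{_annotation(sp_meta, items)}</species>"
            )
        lines.append("</listOfSpecies>")

        # reactions with kegg.reaction / EC links and a kinetic law
        n_rx_links = math.floor(
            config.kegg_reaction_coverage * config.reactions_per_model
        )
        n_ec_links = math.floor(config.ec_coverage * config.reactions_per_model)
        lines.append("<listOfReactions>")
        for ri in range(config.reactions_per_model):
            rx_id = f"Rx{ri}"
            items = []
            if ri < n_rx_links:
                unmatched = rng.random() < config.unmatched_fraction
                rid = "RZZZZZ" if unmatched else rng.choice(kegg_reactions)
                qual = _weighted_choice(rng, config.qualifier_mix)
                items.append(
                    plant(model_id, "reaction", rx_id, qual, "biology",
                          "kegg.reaction", rid, not unmatched)
                )
                if not unmatched:
                    ledger["expected_mapping_rows"][
                        "reactions_process_entities"
                    ].append(
                        {"model": model_id, "element": rx_id,
                         "kegg_reaction": rid, "qualifier": qual}
                    )
            if ri < n_ec_links:
                ec = rng.choice(ec_numbers)
                items.append(
                    plant(model_id, "reaction", rx_id, "isVersionOf",
                          "biology", "ec-code", ec, True)
                )
                ledger["expected_mapping_rows"]["reaction_ec"].append(
                    {"model": model_id, "element": rx_id, "ec": ec,
                     "qualifier": "isVersionOf"}
                )
            sub = f"S{ri % config.species_per_model}" if config.species_per_model else None
            prod = (
                f"S{(ri + 1) % config.species_per_model}"
                if config.species_per_model else None
            )
            rx_meta = f"meta_{model_id}_{rx_id}"
            k = round(rng.uniform(0.1, 9.9), 2)
            body = [_annotation(rx_meta, items)]
            if sub and prod and sub != prod:
                body.append(
                    f'<listOfReactants><speciesReference species="{sub}"/>'
                    "</listOfReactants>"
                    f'<listOfProducts><speciesReference species="{prod}"/>'
                    "</listOfProducts>"
                )
            body.append(
                "<kineticLaw><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
                f"<apply><times/><cn>{k}</cn><ci>{sub or 'x'}</ci></apply>"
                "</math></kineticLaw>"
            )
            lines.append(
                f'<reaction id="{rx_id}" metaid="{rx_meta}" reversible="false">'
                + "".join(body) + "</reaction>"
            )
        lines.append("</listOfReactions>")
        lines.append("</model></sbml>")

        filename = f"{model_id}.xml"
        documents[filename] = "\n".join(lines)
        ledger["models"].append(
            {"sbml_id": model_id, "file": filename, "counts": model_counts}
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for filename, text in documents.items():
            (out_dir / filename).write_text(text)
        (out_dir / "ledger.json").write_text(json.dumps(ledger, indent=2))
    return documents, ledger


def generate_pathway_source(
    ledger: dict, seed: int, out_dir: str | Path,
    *, extra_entities_sharing_first_compound: int = 0,
) -> Path:
    """Write pathway-source TSVs aligned with a corpus ledger.

    Every accession in the ledger's universe becomes exactly one pathway-side
    entity carrying that accession as its external id, so every ledger link
    marked ``matched`` yields a mapping row and no other row can appear.
    *extra_entities_sharing_first_compound* adds molecular entities that
    duplicate the first compound accession, to exercise fan-out.
    """
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    uni = ledger["universe"]

    def write(name: str, header: list[str], rows: list[list[str]]) -> None:
        with open(out_dir / name, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")

    me_rows = [
        [f"ME_{c}", f"metabolite {c}", "compound", f"kegg.compound:{c}"]
        for c in uni["compounds"]
    ]
    first = uni["compounds"][0]
    for j in range(extra_entities_sharing_first_compound):
        me_rows.append(
            [f"ME_{first}_alt{j}", f"conformer {j} of {first}", "compound",
             f"kegg.compound:{first}"]
        )
    write("molecular_entities.tsv", ["id", "name", "type", "external_ids"], me_rows)

    proc_rows = [
        [f"PR_{r}", f"process {r}", "", f"kegg.reaction:{r}"]
        for r in uni["kegg_reactions"]
    ]
    write("processes.tsv", ["id", "name", "ec_numbers", "external_ids"], proc_rows)

    part_rows = []
    for r in uni["kegg_reactions"]:
        for role in ("substrate", "product"):
            c = rng.choice(uni["compounds"])
            part_rows.append([f"PR_{r}", f"ME_{c}", role])
    write(
        "process_participants.tsv",
        ["process_id", "molecular_entity_id", "role"],
        part_rows,
    )

    og_rows = []
    taxa = list(uni["taxa"])
    half = max(1, len(taxa) // 2)
    og_rows.append(["OG1", "eukaryotes A", ";".join(taxa[:half])])
    og_rows.append(["OG2", "eukaryotes B", ";".join(taxa[half:])])
    write("organism_groups.tsv", ["id", "name", "ncbi_taxonomy_ids"], og_rows)

    pw_rows = [
        [f"PW_{p}", f"pathway {p}", "OG1" if i % 2 == 0 else "OG2",
         f"kegg.pathway:{p}"]
        for i, p in enumerate(uni["pathways"])
    ]
    write(
        "pathways.tsv", ["id", "name", "organism_group_id", "external_ids"], pw_rows
    )

    pp_rows = []
    for i, p in enumerate(uni["pathways"]):
        for r in uni["kegg_reactions"][i::len(uni["pathways"])]:
            pp_rows.append([f"PW_{p}", f"PR_{r}"])
    write("pathway_processes.tsv", ["pathway_id", "process_id"], pp_rows)

    go_rows = [
        [t["go_id"], t["name"], ";".join(t["parent_ids"])]
        for t in uni["go_terms"]
    ]
    write("go_terms.tsv", ["go_id", "name", "parent_ids"], go_rows)

    ec_rows = [[e, f"enzyme {e}", ""] for e in uni["ec_numbers"]]
    write("ec_numbers.tsv", ["ec_number", "name", "node_code"], ec_rows)
    return out_dir


def expected_mapping_keys(ledger: dict) -> dict[str, set[tuple]]:
    """Expected mapping rows as comparable key tuples.

    Keys use (model sbmlId, element sbmlId, target id, qualifier) — the
    exact shape the verification queries reconstruct from the store.
    """
    exp = ledger["expected_mapping_rows"]
    return {
        "species_molecular_entities": {
            (r["model"], r["element"], f"ME_{r['compound']}", r["qualifier"])
            for r in exp["species_molecular_entities"]
        },
        "reactions_process_entities": {
            (r["model"], r["element"], f"PR_{r['kegg_reaction']}", r["qualifier"])
            for r in exp["reactions_process_entities"]
        },
        "models_pathways": {
            (r["model"], r["model"], f"PW_{r['pathway']}", r["qualifier"])
            for r in exp["models_pathways"]
        },
        "model_organism": {
            (r["model"], r["model"], r["taxon"], r["qualifier"])
            for r in exp["model_organism"]
        },
        "sbase_go": {
            (r["model"], r["element"], r["go_id"], r["qualifier"])
            for r in exp["sbase_go"]
        },
        "reaction_ec": {
            (r["model"], r["element"], r["ec"], r["qualifier"])
            for r in exp["reaction_ec"]
        },
    }


def generate_random_dag(n: int, edge_prob: float, seed: int) -> Dag:
    """Ranked random DAG: nodes 0..n-1, edge (i, j) for i < j with
    probability *edge_prob* — acyclic by construction, deterministic per
    seed.  Node ids are zero-padded strings so lexicographic and rank order
    agree."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = random.Random(seed)
    width = max(1, len(str(max(0, n - 1))))
    names = [f"n{i:0{width}d}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.add((names[i], names[j]))
    return Dag(nodes=set(names), edges=edges)


def generate_sparse_dag(n: int, mean_extra_edges: float, seed: int) -> Dag:
    """GO-like sparse DAG: a random recursive tree (log depth) plus extra
    forward edges, keeping per-node path counts moderate even at large n."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = random.Random(seed)
    width = max(1, len(str(max(0, n - 1))))
    names = [f"n{i:0{width}d}" for i in range(n)]
    edges = set()
    for j in range(1, n):
        parent = rng.randrange(j)
        edges.add((names[parent], names[j]))
    n_extra = int(mean_extra_edges * n)
    for _ in range(n_extra):
        i = rng.randrange(n - 1)
        j = rng.randrange(i + 1, n)
        edges.add((names[i], names[j]))
    return Dag(nodes=set(names), edges=edges)


def path_count_oracle(dag: Dag) -> dict:
    """Paths from the virtual source to each node, by dynamic programming
    over a topological order (independent of the labeling machinery)."""
    import networkx as nx

    g = dag.to_networkx()
    counts = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        counts[node] = 1 if not preds else sum(counts[p] for p in preds)
    return counts
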