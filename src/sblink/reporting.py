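"""Coverage and growth reports.

``external_link_report`` audits, per model, which external resources the
curation links actually reach: model-level pathway / taxonomy / GO links,
and per-reaction / per-species accession coverage split into with/without
counts (the two always partition the total).  ``growth_stats`` computes
percentage growth between two content snapshots of a database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import LookupFailure, ValidationError
from .store import Store


@dataclass
class CoverageRow:
    model_name: str
    has_kegg_pathway_link: bool
    has_taxonomy_link: bool
    has_go_link: bool
    n_reactions: int
    n_reactions_with_kegg: int
    n_reactions_without_kegg: int
    n_species: int
    n_species_with_kegg: int
    n_species_without_kegg: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GrowthRow:
    item_type: str
    old_count: int
    new_count: int
    pct_increase: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def external_link_report(
    store: Store,
    model_ids: list[str] | None = None,
    *,
    biological_process_terms: set[str] | None = None,
) -> list[CoverageRow]:
    """Per-model external-link coverage.

    A model-level boolean is true iff the model element itself carries at
    least one link in the respective namespace; a reaction counts as "with
    KEGG" iff it carries >=1 kegg.reaction link, a species iff >=1
    kegg.compound link.  When *biological_process_terms* is given, the GO
    boolean only counts links to terms in that set (GO subontology is not
    derivable from an accession alone).
    """
    models = {r["id"]: r for r in store.models()}
    if model_ids is None:
        model_ids = sorted(models, key=lambda m: models[m]["sbmlId"])
    for mid in model_ids:
        if mid not in models:
            raise LookupFailure(f"unknown model id {mid!r}")

    links = store.annotation_links()
    model_ns: dict[str, set[str]] = {}
    model_go_ids: dict[str, set[str]] = {}
    reactions_with: dict[str, set[str]] = {}
    species_with: dict[str, set[str]] = {}
    for link in links:
        mid, kind, ns = link["modelId"], link["kind"], link["namespace"]
        if kind == "model":
            model_ns.setdefault(mid, set()).add(ns)
            if ns == "obo.go":
                model_go_ids.setdefault(mid, set()).add(link["externalId"])
        elif kind == "reaction" and ns == "kegg.reaction":
            reactions_with.setdefault(mid, set()).add(link["sbaseId"])
        elif kind == "species" and ns == "kegg.compound":
            species_with.setdefault(mid, set()).add(link["sbaseId"])

    rows = []
    for mid in model_ids:
        model = models[mid]
        n_reactions = len(store.reactions_of_model(mid))
        n_species = len(store.species_of_model(mid))
        n_rx_with = len(reactions_with.get(mid, ()))
        n_sp_with = len(species_with.get(mid, ()))
        go_ids = model_go_ids.get(mid, set())
        if biological_process_terms is not None:
            go_ids = go_ids & biological_process_terms
        rows.append(
            CoverageRow(
                model_name=model["name"] or model["sbmlId"],
                has_kegg_pathway_link="kegg.pathway" in model_ns.get(mid, ()),
                has_taxonomy_link="taxonomy" in model_ns.get(mid, ()),
                has_go_link=bool(go_ids),
                n_reactions=n_reactions,
                n_reactions_with_kegg=n_rx_with,
                n_reactions_without_kegg=n_reactions - n_rx_with,
                n_species=n_species,
                n_species_with_kegg=n_sp_with,
                n_species_without_kegg=n_species - n_sp_with,
            )
        )
    return rows


def growth_stats(
    old_counts: dict[str, int], new_counts: dict[str, int]
) -> list[GrowthRow]:
    """Percentage increase per item type: 100 * (new - old) / old.

    Every item type must appear in both maps with a positive old count.
    """
    rows = []
    for item_type, old in old_counts.items():
        if item_type not in new_counts:
            raise ValidationError(f"item type {item_type!r} missing from new counts")
        if old <= 0:
            raise ValidationError(
                f"item type {item_type!r}: old count must be positive, got {old}"
            )
        new = new_counts[item_type]
        rows.append(
            GrowthRow(
                item_type=item_type,
                old_count=old,
                new_count=new,
                pct_increase=100.0 * (new - old) / old,
            )
        )
    return rows


def write_report(rows, path: str | Path, fmt: str = "tsv") -> None:
    """Emit a coverage or growth report as TSV or JSON."""
    path = Path(path)
    dicts = [r.as_dict() for r in rows]
    if fmt == "json":
        path.write_text(json.dumps(dicts, indent=2) + "\n")
        return
    if not dicts:
        path.write_text("")
        return
    cols = list(dicts[0])
    lines = ["\t".join(cols)]
    for d in dicts:
        lines.append("\t".join(str(d[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")
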