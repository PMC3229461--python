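# Methods

## Data model

The store follows a loose-coupling design: model-side tables (parsed from
SBML documents) and pathway-side tables (KEGG-like molecular entities,
process entities, pathways, GO terms, EC numbers, organism groups) never
share rows. Integration happens only through mapping tables whose rows
are derived mechanically from MIRIAM annotations; the mapping step never
creates or edits an entity on either side (no curation). This keeps
reloads of either source independent and makes every mapping row
traceable to one annotation link, qualifier included.

Model-side entities all extend a single `Sbase` base (id, metaId,
sboTerm, notes, raw annotation XML). The internal id is opaque —
UUID4 by default, or a UUID5 over `(data source, model sbmlId, element
kind, element sbmlId)` in deterministic mode so re-ingest is idempotent
and tests are reproducible. The SBML `id` attribute is stored separately
as `sbmlId` because it is frequently the only meaningful name an element
has. One deviation from a flat transliteration of the schema: the
stoichiometry pair (`float` value or MathML expression) lives directly on
the `ReactionSpecies` row rather than behind an extra one-row table; the
two fields are mutually exclusive by contract, and at least one is set
for reactants and products (modifiers carry neither).

### SBML ingest

SBML Level 2, versions 1–4, parsed with lxml. Only the entity kinds of
the relational model are materialized; anything else survives verbatim in
the stored document text. Parsing rules that matter:

* Missing optional attributes stay absent (NULL), except the SBML-defined
  defaults `reversible=true`, `fast=false`, `constant=false` (species) /
  `true` (compartments, parameters), `boundaryCondition=false`,
  `hasOnlySubstanceUnits=false`, and default stoichiometry 1.
* MathML is whitespace-canonicalized text (`>\s+<` collapsed, runs of
  whitespace folded). No evaluation, no algebraic rewriting.
* The 31 built-in base units are seeded before any ingest with NULL
  model id; user units must compose base units only — a user unit defined
  over another user unit is a validation error.
* Identifiers inside MathML are classified species / parameter /
  compartment / function by lookup; function references carry the
  function definition's internal id (the `function_id` argument
  attribute). Unresolved identifiers are flagged, never fatal.
* Errors: malformed XML names the line; level ≠ 2 is rejected; duplicate
  `sbmlId` within a model is an integrity error.

### MIRIAM extraction

A URN splits as `urn:miriam:<namespace>:<id>` on the first colon after
the scheme (namespaces never contain colons); the id is percent-decoded
exactly once and keeps its case, while namespaces are compared
case-insensitively and stored lowercase. Qualifier elements are
recognized by XML namespace: the model-qualifier namespace maps to the
`model` family, everything else (normally the biology-qualifier
namespace) to `biology`. Unknown local names map to the `unknown`
qualifier rather than failing. The persisted qualifier dimension is
pre-filled with eleven names (`is`, `isDescribedBy`, `encodes`,
`hasPart`, `hasVersion`, `isEncodedBy`, `isHomologTo`, `isPartOf`,
`isVersionOf`, `occursIn`, `unknown`); the remaining standard qualifiers
(`hasProperty`, `isPropertyOf`, `hasTaxon`, `isDerivedFrom`) are accepted
and inserted on first use. Extraction is deliberately forgiving: an
annotation that is not parseable XML, or a resource that is not a MIRIAM
URN, is skipped with a logged warning — a corpus ingest must survive
messy annotations.

### Mapping rules

| link subject | namespace | target table |
|---|---|---|
| species | `kegg.compound`, `obo.chebi` | MapSpeciesMolecularEntities |
| reaction | `kegg.reaction` | MapReactionsProcessEntities |
| model | `kegg.pathway` | MapModelsPathways (organism group copied from the pathway) |
| model | `taxonomy` | ModelOrganism (group resolved through the pathway store when the taxon belongs to one) |
| any Sbase | `obo.go` | MapSbaseGO (skipped+logged if the term is not loaded) |
| reaction | `ec-code` | MapReactionECNumber (skipped+logged if the EC number is not loaded) |

Fan-out is allowed in both directions (one accession shared by two
molecular entities — e.g. two optical conformations of glucose — yields
two rows; one species with two compound links yields two rows). Rows
deduplicate on the full (entity, target, qualifier) key, so the same pair
under two qualifiers keeps both rows. Links with no index match produce
no row and are counted as unmatched. Reactome links are extracted and
stored as annotation links but feed no mapping table (there is no
Reactome-side store).

## NodeCodes labeling

Codes are tuples of non-negative integers serialized with a `.`
delimiter (`"0.13.2"`); the virtual source's single code is the empty
tuple, serialized `""`. Delimited components — not concatenated digits —
are required for the prefix property to survive nodes with ten or more
children. Assignment walks the DAG in FIFO topological (Kahn) order:
a plain breadth-first pass would let a multi-parent node propagate an
incomplete code set, so topological order is the correctness-preserving
reading of level-wise traversal on a DAG. Sibling order is lexicographic
node id, purely for determinism. A configurable cap (default 10⁷ total
codes) guards against path-count explosion on dense DAGs; ontology-like
sparse DAGs stay orders of magnitude below it.

Query semantics are strict: `is_descendant(u, v)` is true iff some code
of *u* is a *proper* component-wise prefix of some code of *v*, so a node
is never its own descendant. The browse layer re-adds the query term
itself where the user expects "descendants of *t* and *t*". Descendant
retrieval sorts all `(code, node)` pairs once; the extensions of a code
*x* form a contiguous run of that order, located with two binary searches
(`x` exclusive to the successor of `x`'s last component), so a query
touches no adjacency structure. Ancestor retrieval inverts the code→node
map over the proper prefixes of the term's codes. The instrumented
iterative baseline (children-closure DFS reporting its visited-node
count) is retained both as the correctness oracle and to expose the cost
contrast: its per-query work is bounded below by the result size, while
the labeled method's adjacency-traversal count is identically zero.

## Store

SQLite (stdlib `sqlite3`), single file, schema shipped as
`src/sblink/schema.sql`. All access flows through the `Store` wrapper —
per-table accessors, no SQL strings in caller code — and `Store.open`
maintains one live handle per database file. Foreign keys are enabled
with `ON DELETE CASCADE` throughout; because entity tables hang off
`Sbase` by inheritance (their `id` references `Sbase.id`), deleting a
model removes its whole `Sbase` closure and lets the engine cascade
through entity, participant, kinetic-law, event, mapping and annotation
rows, leaving pathway-side rows untouched. An internal `SbaseIndex`
(sbaseId → model, entity kind) supports the closure computation, the
GO-browse join and the orphan sweep; `PRAGMA foreign_key_check` plus an
unclaimed-Sbase scan implements that sweep.

Twelve small dimension tables (`Attribute`, `EntityName`, `GraphNode`,
`MolecularEntityType`, `NameId`, `NameType`, `PathwaysType`,
`ProcessEntityRole`, `ReactionSpeciesRole`, `RnaType`, `RuleType`,
`UnitDefinition`) are cached fully in memory and rebuilt on any write to
a cached table. The cache is a pure optimization — every query returns
identical results with it disabled (tested) — and a cache hit performs
zero engine reads (instrumented counter). The flux-expression query
groups kinetic laws by canonicalized MathML text only; algebraic
equivalence of rate laws is undecidable in general and out of scope. The
result columns of the built-in queries are this package's choice except
for the species-with-role column, which is fixed by its contract.

## Synthetic fixtures

The generators emulate the *structure* of a curated model repository:
per-model entity counts, the RDF/URN annotation grammar, per-namespace
coverage fractions, and a controllable fraction of links that reference
accessions absent from the pathway side. Defaults (10 models, 5 species
and 4 reactions per model, compound coverage 0.6, reaction coverage 0.5,
EC 0.25, pathway/taxonomy/GO model-level fractions 0.6/0.9/0.8) are fixed
study conditions chosen to resemble small curated corpora in which most
metabolic entities carry accessions and a minority of models lack
pathway links. Planted link counts use the floor rule
`floor(coverage × n_entities)` so ledgers are exact. The aligned
pathway-source generator gives every universe accession exactly one
pathway-side owner (plus optional deliberate duplicates to exercise
fan-out), which makes expected mapping rows fully decidable from the
ledger — the basis of the precision/recall checks. Seeds are mandatory
arguments; there is no unseeded generation path.

What the fixtures do **not** emulate: biologically meaningful
stoichiometry or kinetics, realistic GO/EC hierarchies at scale, or the
noise of hand-written annotations (encoding variants, stale accessions).
Passing tests therefore demonstrate the mechanics of parsing, mapping and
querying, not robustness to every curation artifact in the wild.

Two DAG generators serve different regimes: a ranked Erdős–Rényi model
(edge *i*→*j*, *i*<*j*, with fixed probability) for small oracle-checked
instances, and a GO-like sparse model (random recursive tree, hence
logarithmic depth, plus a fraction of extra forward edges) whose per-node
path counts stay moderate at large *n* — the regime in which path-set
labeling is the right tool. Large-scale checks use 20,000 nodes with 0.3
extra edges per node and 1,000 sampled query terms; the oracle-agreement
battery uses 100 seeded DAGs (95 Erdős–Rényi with n between 5 and 150 and
edge probability 3/n, five sparse ones up to n = 2,000) compared against
a reverse-topological set-union closure computed independently of the
labeling code; the path-count law is brute-force-checked on DAGs with
n ≤ 12 by exhaustive path enumeration. These sizes are the package's
reference study conditions.

## Design choices and limitations

* Percent-decoding is applied once and only to the id segment of a URN;
  double-encoded ids would decode to a single-encoded form by design.
* Species↔entity matching uses `kegg.compound` and `obo.chebi` with no
  precedence: a species matching one entity through both namespaces under
  the same qualifier still collapses to one row per qualifier.
* `CompartmentClass` hierarchies and the compartment-name dictionary have
  no upstream source here; they are seeded only from fixtures.
* The GO coverage boolean cannot see subontologies from a bare accession;
  callers may pass the biological-process term set to restrict it.
* Relabeling is full-rebuild only; incremental maintenance after graph
  edits, and interval/prefix-compressed labeling alternatives, are out of
  scope.
* Wall-clock benchmark numbers are hardware-dependent; correctness
  properties and operation counts (visited nodes vs. zero adjacency
  traversals) are the portable claims, and `run_query_benchmark` asserts
  result-set equality before it times anything.
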