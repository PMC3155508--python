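# Methods

## Scope and design

The package implements a management layer for Linked Data organized
under a knowledge-organization core model: a small query language with
two interconvertible flavours, a quad store of typed named graphs, an
access-control algebra with propagation, SPARQL serialization of
selects, and identifier dereferencing across multiple deployments
simulated in one process. The core model is data-driven: the default
(S3DB-style, seven entities, twelve relationships) and a minimal SKOS
core ship as JSON descriptions under `s3ql/cores/`, and any model of the
same shape can be loaded in their place. JSON was chosen for the
description files because the format must be hand-editable and
round-trip exactly (`save(load(d)) == d` is tested).

### The transition matrix

The twelve default relationships are directed parent→child and double as
the permission transition matrix once instantiated on a store's content:

| code | from → to | instantiating attribute |
|------|-----------|------------------------|
| DD | Deployment → Deployment | `deployment_id` (root registry) |
| DU | Deployment → User | structural |
| DP | Deployment → Project | structural |
| PP | Project → Project | `project_id` (subproject) |
| PC | Project → Collection | `project_id` |
| PR | Project → Rule | structural (via subject collection) |
| CR | Collection → Rule | `subject_id` (rdfs:domain) |
| OR | Collection → Rule | `object` (rdfs:range, when a collection) |
| CI | Collection → Item | `collection_id` |
| RS | Rule → Statement | `rule_id` |
| IS | Item → Statement | `item_id` |
| SS | Statement → Statement | `value` (statement reuse) |

This set is a reconstruction fixed from the facts available in the
model's public descriptions (the PC dependency, rule domain/range,
statement instantiation, root deployments); because the matrix is part
of the core-model file, a corrected set is a configuration change, not a
code change.

## The store

Every instance is a named graph whose name is the entity URI
(`<deployment-url>/<UID>`). Contextual descriptors live in the default
graph: `rdf:type`, an `id` literal, `rdfs:label`, `dcterms:description`,
`dcterms:created` (UTC ISO 8601) and `dcterms:creator`. `id`, `created`
and `creator` are system-assigned at insert time and immutable; updates
touch submitter attributes only and append a change note (timestamp,
modifier, optional comment). Deletion is soft — a `deprecated` flag —
so cross-references never dangle and deprecated content can still be
exported on request. Rule graphs contain their single domain triple
(with a verb URI minted under the rule's own fragment, so renaming the
verb rewrites only the rule graph); statement graphs contain the
instantiating triple whose predicate is the rule's graph name.
Rule/statement attribute values are additionally kept as contextual
triples in the default graph; this duplication makes import
reconstruction and attribute-level queries trivial and costs a few quads
per instance.

Export/import uses rdflib (TriG and N-Quads losslessly; Turtle as a
documented lossy single-graph convenience). No blank nodes are minted,
so store equality is decided on sorted canonical N-Quads; the same
canonical form underwrites fixture determinism.

## The language

The grammar covers `action(E | E.a = value, …)` with four actions,
entity letters or full names (case-insensitive), an optional single
projection `E.a`, conjunctive parameters, and bare-UID shorthand:
a bare `P156` on a Collection target means `project_id = 156` (the
letter is resolved through the core model's relationships into the
target). In the permission-assignment form `insert(U|U1,P157,
permission_level=ysn)` the two bare UIDs are the subject user and the
target entity. The XML flavour is `<S3QL><action>entity</action>
<where>…</where></S3QL>`; a projection is rendered as
`<select>entity.attr</select>` (the flavour interconversion must be
lossless and the reference examples show no projection in XML, so this
extension was fixed by the implementation). Parsing is lenient about
attribute names (so that a query written for one core can be *validated*
against another and produce a named violation rather than a parse
failure); `validate()` is the strict check.

## The permission algebra

Each position symbol merges as the join of the total order
`- < y < s < n < Y < S < N`: dominance (case) decides first, then
restrictiveness `N > S > Y`; `-` is the identity. Two dominant (or two
recessive) symbols therefore resolve most-restrictive — the safe choice
for biomedical privacy, and consistent with every published merge
outcome (a dominant `N` beating a recessive `y`; nothing ever shows `Y`
beating `N`). Because the merge is a semilattice join, it is
commutative, associative and idempotent (tested exhaustively), and
propagation has a least fixpoint.

Propagation (the default *merge* kernel) copies each assigned state
along every matrix edge and joins at each node; with unlimited memory
the effective state of a node is the join of the assigned states of all
its ancestors and itself, computed by a worklist fixpoint and verified
against a brute-force path-enumeration oracle on random stores. A
`memory_length` bound limits how many hops a state travels (the default
is unlimited, which reproduces all worked examples); an alternate
*migrate* kernel moves a state to strict descendants without keeping it
at its origin and is provided behind a flag only. Propagated states keep
their case — a dominant `N` arrives dominant. A position still `-`
after propagation denies: users with no derivable rights see nothing.

Gating: `select`→view, `update`/`delete`→change, `insert`→use, with
`S`/`s` honoured only for the target's creator. Inserting a child
requires use on *every* linked parent (statement inserts need the rule
and the item) — the conservative reading where the examples do not
decide. One assigned state exists per (user, target); re-assignment
replaces it. A directly assigned `N` leaves the entity's bare reference
visible in parent listings (as permission-management UIs display it)
while a propagated `N` hides the entity outright; both hide content.
The deployment record's creator acts as the deployment admin and
bypasses gating, as does the internal trusted caller (`user=None`).

## Federation

Deployments are full store instances addressed by URL through an
in-process `Network` transport; an optional HTTP facade would bind to
the same surface but is not required for the semantics and is not built.
A root deployment's registry is just its store's Deployment records, so
registration and lookup are ordinary `insert(D|…)` / `select(D.url|D…)`
queries. Resolution of a qualified UID walks the qualifier chain
root-first, caching each answer locally for 24 hours (configurable);
the cache changes cost, never results, which the tests check by
comparing cold and warm resolutions and counting lookups. Surrogate
tokens are opaque random strings bound server-side to (user, expiry),
with a 1-hour default TTL; validation at a foreign deployment delegates
to the user's home deployment (resolved through the root) and expiry is
reported distinctly from mismatch. A federated select resolves the
holder, validates the requester, strips the qualifier, executes locally
under the holder's own gating, and returns nothing on any
authentication failure.

## Fixtures and what they do (not) show

`gi_trials` instantiates the clinical-trials permission scenarios: two
users with project-wide `ysn`, one restricted by `N--` on Demographics,
one granted `--Y` (use) on TissueData. `mlst_mini` builds a three-
deployment federation (root registry, user home, typing-data holder with
rule `R172930` over strain allele-profile statements). Labels and
values are invented minimally to instantiate the structures; statement
values are drawn from a seeded generator. Determinism comes from a
stepped simulation clock plus per-deployment seeded RNGs: identical
(scenario, seed) gives byte-identical canonical exports. The `random`
scenario grows stores of up to ~30 entities for the propagation oracle.
These fixtures exercise structure and semantics, not scale or
concurrency: passing tests say nothing about multi-writer conflicts,
real network failure modes, or stores beyond desk scale.

## Numerical and procedural choices

* Timestamps UTC ISO 8601; the simulation clock starts at a fixed epoch
  and steps 1 s per observation.
* UID numbering is sequential per deployment from 1; explicit numbers
  may be supplied at the store API (used to reproduce reference-style
  identifiers such as `R172930` and registry entries such as `D282`).
* Entity URI = deployment URL + `/` + UID. (The reference material
  itself maps `http://q.s3db.org/demo` to a `/s3dbdemo/P126` URI; the
  simple convention is adopted and the discrepancy noted.)
* Literal values are stored untyped unless a rule's object names a
  collection, in which case item-valued statements are range-checked.
* Operator states are minted as predicates under
  `http://s3db.org/operator#`, e.g. `op:ysn`.
* The propagation oracle in the test suite enumerates ancestors with
  networkx on DAGs only; the engine's fixpoint also terminates on cyclic
  matrices (finite lattice, monotone join) but the oracle comparison is
  restricted to the acyclic stores the generators produce.
* Problem sizes: property suites use 50 random stores of 8–30 entities
  and exhaustive 7×7×7 symbol tables; these sizes fully cover the
  algebra and keep the whole suite under a few seconds.

## Known limitations

* SPARQL emission covers selects only, and `sparql_to_s3ql` accepts a
  single rule-predicate triple pattern (joins are rejected with a named
  unsupported-fragment error).
* Select filters traverse the one-hop paths shown in the worked
  examples (collections/rules of a project, statements of a rule, …);
  deeper traversal would be an extension.
* Authentication is the token-stub contract; real credential protection
  (OAuth, TLS, signed registry updates) is out of scope.
* Deployment metadata is a minimal record (ref, URL, title,
  description), not full VoiD coverage.
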