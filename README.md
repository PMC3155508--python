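# s3ql-kos

Controlled read/write management of Linked Data organized under a
pluggable knowledge-organization core model, with the S3DB
(Simple Sloppy Semantic Database) core as the default.

Life-sciences groups that publish evolving, partly sensitive datasets as
RDF need more than a SPARQL endpoint: they need to *write* — insert,
update and deprecate instances — with provenance stamped automatically,
and to share a single consolidated dataset with collaborators whose
rights differ per collection, without splitting it into public and
private copies. This package implements that management layer as a small
domain-specific query language (S3QL) over a quad store of typed named
graphs, with a permission-operator algebra that propagates rights over
the model's dependency structure, SPARQL serialization of selects, and
identifier dereferencing across multiple (simulated) deployments.

## The model in brief

**Entities as typed named graphs.** The default core model declares
seven entity types — Deployment (D), User (U), Project (P), Collection
(C), Rule (R), Item (I), Statement (S) — each instance a named graph
carrying five contextual descriptors (`id`, `label`, `description`,
`creator`, `created`; the first and last two system-assigned). Instances
get compact UIDs (`P126`), optionally deployment-qualified
(`D282:P126`, recursively `D1016666:D327:R172930`).

**Domain separated from instantiation.** A rule graph holds one domain
triple, e.g. `[Person hasAge Age]` identified as `:R12`; a statement
instantiating it uses the rule's graph name as its predicate:
`[John :R12 26]`. Editing the verb never touches existing statements.

**Four actions, three operators.** S3QL has exactly four operations —
`select`, `insert`, `update`, `delete` — written compactly as
`action(E | E.a = value, …)` or as equivalent XML. Rights are
three-position operator strings over `{Y,S,N,y,s,n,-}` governing
*view* / *change* / *use*: `Y` full, `S` creator-only, `N` none;
uppercase dominant, lowercase recessive, `-` unassigned. `select` is
gated by view, `update`/`delete` by change, `insert` by use on each
parent the new instance links to. States assigned on one entity
propagate along the twelve-relationship transition matrix
(project → collection → rule/item → statement, …), merging wherever they
converge: per position the join of the order
`- < y < s < n < Y < S < N`. The assigned `ysn` on a project with `N--`
on one collection therefore yields the effective `Nsn` on that
collection and everything depending on it.

## Worked example

```python
from s3ql import execute, generate_fixture, merge, parse_compact, parse_state

gi = generate_fixture("gi_trials", seed=0)   # demo clinical-trials project
store = gi.store
print(merge(parse_state("ysn"), parse_state("N--")))   # -> Nsn

eff = store.effective_permissions(gi.refs["gi_user1"])
print(eff[gi.refs["demographics"].uid])                # -> Nsn
print(eff[gi.refs["tissue"].uid])                      # -> ysn

q = parse_compact("insert(I|C2,label=new-sample)", store.core)
execute(q, store, user=gi.refs["gi_user2"]).ref        # -> I5 (use granted)
execute(q, store, user=gi.refs["gi_user1"])            # PermissionDenied: use=n
```

The dominant `N--` assigned to gi_user1 on the *Demographics* collection
overrides the recessive project-wide `ysn`, hiding that collection's
rules, items and statements from every select the user issues, while the
sibling *TissueData* collection stays visible (`ysn`). gi_user2's
explicit use grant (`--Y`) on TissueData permits inserting new items
there; gi_user1 is refused at the `use` position.

The same library surface drives translation
(`translate("insert(P | label = Test)")` emits the canonical XML block),
SPARQL serialization (`select(S|R390)` ⇄ `?Patient :R390 ?cancerType`)
and federation (`resolve("D282:P126")`, token-validated
`federated_select`). The `examples/` directory holds one narrative
script per capability; a thin `s3ql` CLI (`translate`, `query`,
`permissions`, `sparql`, `fixture`, `export`, `import`) wraps the same
functions for shell use.

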