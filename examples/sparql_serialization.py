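"""Serialize statement selects to SPARQL and back.

Because the domain is represented as rules whose graph names act as the
predicates of instantiating statements, a statement select maps to a
single SPARQL triple pattern whose predicate is the rule UID — and such
patterns map back.  SPARQL is entailed by the query language, not the
opposite: writes and permission operations have no SPARQL form.
"""

from rdflib import Dataset

from s3ql import (
    execute,
    generate_fixture,
    parse_compact,
    sparql_to_s3ql,
    to_compact,
    to_sparql,
)

mlst = generate_fixture("mlst_mini", seed=0)
data = mlst.deployments["D327"]

q = parse_compact("select(S.value|R172930)", data.store.core)
sparql = to_sparql(q, data.store.core, base_url=data.url)
print("S3QL:  select(S.value|R172930)\nSPARQL:\n" + sparql + "\n")

# Run the emitted SPARQL over the exported quads with rdflib and compare
# with direct execution: the same allele-profile values come back.
ds = Dataset(default_union=True)
ds.parse(data=data.store.export_quads("trig"), format="trig")
print("via SPARQL:", sorted(str(r[0]) for r in ds.query(sparql)))
print("via execute:", sorted(r["value"] for r in execute(q, data.store).rows))

back = sparql_to_s3ql("?Patient :R390 ?cancerType", data.store.core)
print("\n'?Patient :R390 ?cancerType' serializes to:", to_compact(back, data.store.core))
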