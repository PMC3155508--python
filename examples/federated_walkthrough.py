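"""Cross-deployment dereferencing and a federated, authenticated select.

Three in-process deployments: a root registry (D1016666), a home
deployment (D309) holding user U78, and a data deployment (D327) holding
typing-profile statements under rule R172930.  The qualified UID
``D327:R172930`` is dereferenced at the root (``select(D.url|D327)``),
the query re-issued at the holder with the qualifier stripped, and the
requesting user validated back at their home deployment with the
surrogate token before any rows are returned.
"""

from s3ql import Credential, generate_fixture
from s3ql.errors import AuthenticationError

mlst = generate_fixture("mlst_mini", seed=0)
home = mlst.deployments["D309"]

url, uri = home.resolve("D327:R172930")
print(f"D327:R172930 dereferences to {uri} (deployment at {url})")
print(f"registry lookups so far: {home.lookup_count}")

url2, _ = home.resolve("D1016666:D327:R172930")
print(f"recursive form resolves root-first; lookups now: {home.lookup_count}")
# The second resolve hits the local 24-hour cache for D327, so only the
# foreign-root lookup was added.

cred = home.issue_token(mlst.refs["user"])
rows = home.federated_select("select(S.value|D327:R172930)", cred).rows
print(f"\nfederated select returned {len(rows)} allele profiles:")
for row in rows:
    print(" ", row["value"])

forged = Credential(cred.user, "forged-token", cred.issued, cred.ttl)
try:
    home.federated_select("select(S.value|D327:R172930)", forged)
except AuthenticationError as exc:
    print(f"\nforged token -> {exc} (no data returned)")
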