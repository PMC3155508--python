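"""Operator states, merging and propagation on the clinical-trials demo.

Builds the gi_trials fixture (one project, three collections, two users)
and shows how the assigned three-position states (view/change/use)
propagate down the transition matrix: gi_user1 inherits 'ysn' from the
project everywhere, but a dominant 'N--' assigned on the Demographics
collection merges to an effective 'Nsn' on it and on every rule and
item that depends on it — the user can no longer view that data.
"""

from s3ql import execute, generate_fixture, merge, parse_compact, parse_state
from s3ql.errors import PermissionDenied

gi = generate_fixture("gi_trials", seed=0)
store = gi.store
u1, u2 = gi.refs["gi_user1"], gi.refs["gi_user2"]

print("merge('ysn', 'N--') =", merge(parse_state("ysn"), parse_state("N--")))
# -> Nsn: the dominant N overrides the recessive y at the view position;
#    the unassigned '-' positions fall back to the inherited s and n.

eff = store.effective_permissions(u1)
for name in ("project", "demographics", "tissue", "rule_name", "patient1"):
    ref = gi.refs[name]
    rec = store.records[ref.uid]
    print(f"gi_user1 effective on {rec.label or name:<18} ({ref.uid}): {eff[ref.uid]}")

# The third position, 'use', gates inserts of child entities:
q = parse_compact(f"insert(I|{gi.refs['tissue'].uid},label=new-sample)", store.core)
try:
    execute(q, store, user=u1)
except PermissionDenied as exc:
    print(f"gi_user1 insert into TissueData denied ({exc})")
result = execute(q, store, user=u2)
print(f"gi_user2 insert into TissueData allowed -> new item {result.ref}")
# gi_user2 holds an explicit dominant use grant ('--Y') on TissueData,
# which beats the recessive 'n' inherited from the project.
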