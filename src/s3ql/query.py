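"""Query execution under permission gating, and SPARQL serialization.

``execute`` is the single entry point through which S3QL operations
touch a store: selects filter by parameters and then by the acting
user's effective *view* permission; writes route through the operator
gate (*change* for update/delete, *use* on every linked parent for
insert) and stamp contextual descriptors in one transaction.

Statement selects serialize to SPARQL: the rule's graph name is the
triple pattern's predicate, constrained to statement-typed named graphs.
The reverse direction, :func:`sparql_to_s3ql`, covers the
single-rule-predicate fragment (``?Patient :R390 ?cancerType`` becomes
``select(S|R390)``); SPARQL is entailed by S3QL but not the opposite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core_model import CoreModel, EntityRef, EntityType
from .errors import (
    NotFoundError,
    PermissionDenied,
    UnsupportedFragmentError,
    UnsupportedOperationError,
    ValidationError,
)
from .language import S3QLQuery
from .permissions import ACTION_POSITION, UNASSIGNED, authorize, parse_state
from .store import Store


@dataclass
class ResultSet:
    """Rows visible to the acting user, optionally projected."""

    rows: list[dict]
    entity: str
    projection: str | None = None

    def __len__(self):
        return len(self.rows)

    def values(self, key: str | None = None) -> list:
        key = key or self.projection
        return [r.get(key) for r in self.rows]


@dataclass
class WriteResult:
    action: str
    ref: EntityRef | None
    detail: str = ""


def _is_admin(store: Store, user) -> bool:
    if user is None:
        return True
    dep = store.records.get(store.deployment.uid) if store.deployment else None
    return dep is not None and dep.creator is not None and str(dep.creator) == str(user)


def _effective(store: Store, user):
    return store.effective_permissions(user)


def _visible(store: Store, user, eff, rec) -> str:
    """'full', 'bare' (listed by reference only) or 'hidden'."""
    state = eff.get(rec.uid, UNASSIGNED)
    sym = state.view
    if sym in "Yy":
        return "full"
    if sym in "Ss":
        return "full" if (rec.creator and str(rec.creator) == str(user)) else "hidden"
    # a *directly assigned* N keeps the bare ref visible in parent listings;
    # a propagated N hides the entity outright
    if (str(user), rec.uid) in store.permissions:
        return "bare"
    return "hidden"


def _select_filters(q: S3QLQuery, entity: EntityType, store: Store) -> dict:
    filters = {}
    for key, value in q.params:
        if key == "key":
            continue
        filters[key] = value
    # supported one-hop traversal: rules of a project go via their subject
    # collection (select(R|P...))
    if entity.name == "Rule" and "project_id" in filters:
        want = str(filters.pop("project_id"))
        collections = {r.uid for r in store.select("Collection")
                       if str(r.attrs.get("project_id")) == want}
        filters["__subject_in__"] = collections
    return filters


def execute(q: S3QLQuery, store: Store, user: EntityRef | str | None = None,
            now=None) -> ResultSet | WriteResult:
    """Execute one validated S3QL query against ``store`` as ``user``.

    ``user=None`` means a trusted internal caller (no gating); the
    deployment's creating user is likewise fully permitted.
    """
    core = store.core
    entity = core.entity(q.entity)
    if q.action == "select":
        return _execute_select(q, store, user, entity)
    if q.action == "insert":
        return _execute_insert(q, store, user, entity, now)
    if q.action in ("update", "delete"):
        return _execute_change(q, store, user, entity, now)
    raise UnsupportedOperationError(f"unknown action {q.action!r}")


def _execute_select(q, store, user, entity) -> ResultSet:
    filters = _select_filters(q, entity, store)
    subject_in = filters.pop("__subject_in__", None)
    records = store.select(entity, filters)
    if subject_in is not None:
        records = [r for r in records
                   if isinstance(r.attrs.get("subject_id"), EntityRef)
                   and r.attrs["subject_id"].uid in subject_in]
    gate = not _is_admin(store, user)
    eff = _effective(store, user) if gate else {}
    rows = []
    for rec in records:
        if gate:
            vis = _visible(store, user, eff, rec)
            if vis == "hidden":
                continue
            if vis == "bare":
                rows.append({"id": rec.uid})
                continue
        row = rec.row()
        if q.projection:
            row = {q.projection: row.get(q.projection)}
        rows.append(row)
    return ResultSet(rows, entity.name, q.projection)


def _require(decision, action, target):
    if not decision.allowed:
        raise PermissionDenied(
            f"{action} on {target} denied: {decision.reason}", position=decision.position)


def _execute_insert(q, store, user, entity, now) -> WriteResult:
    params = dict(q.params)
    params.pop("key", None)
    # permission-assignment form: insert(U|U1,P157,permission_level=ysn)
    if entity.name == "User" and "permission_level" in params:
        state = parse_state(str(params["permission_level"]))
        subject = params.get("user")
        target = params.get("entity")
        if subject is None or target is None:
            raise ValidationError(
                "permission assignment needs a user UID and a target entity UID")
        if not _is_admin(store, user):
            eff = _effective(store, user)
            rec = store.get(target)
            dec = authorize("insert", eff.get(rec.uid, UNASSIGNED),
                            rec.creator is not None and str(rec.creator) == str(user))
            _require(dec, "permission assignment", target)
        store.assign_permission(subject, target, state)
        return WriteResult("insert", None, f"[{subject} {state} {target}]")
    # ordinary insert: 'use' must be granted on every linked parent
    if not _is_admin(store, user):
        eff = _effective(store, user)
        parents = [v for k, v in params.items()
                   if isinstance(v, EntityRef) and not v.qualifiers]
        if not parents:
            raise PermissionDenied(
                f"insert of {entity.name} denied: no parent grants 'use'", position="use")
        for parent in parents:
            rec = store.get(parent)
            dec = authorize("insert", eff.get(rec.uid, UNASSIGNED),
                            rec.creator is not None and str(rec.creator) == str(user))
            _require(dec, "insert", parent)
    number = None
    if entity.name == "Deployment" and "deployment_id" in params:
        number = EntityRef.parse(str(params.pop("deployment_id"))).number
    user_ref = EntityRef.parse(user) if isinstance(user, str) else user
    ref = store.insert_entity(entity, params, acting_user=user_ref, now=now, number=number)
    return WriteResult("insert", ref)


def _execute_change(q, store, user, entity, now) -> WriteResult:
    params = dict(q.params)
    params.pop("key", None)
    self_key = f"{entity.name.lower()}_id"
    target = params.pop(self_key, None) or params.pop("id", None)
    if target is None:
        raise ValidationError(f"{q.action} needs the target's UID (e.g. {entity.letter}12)")
    target_ref = EntityRef.parse(str(target))
    rec = store.get(target_ref)
    if not _is_admin(store, user):
        eff = _effective(store, user)
        dec = authorize(q.action, eff.get(rec.uid, UNASSIGNED),
                        rec.creator is not None and str(rec.creator) == str(user))
        _require(dec, q.action, target_ref)
    user_ref = EntityRef.parse(user) if isinstance(user, str) else user
    if q.action == "update":
        comment = params.pop("comment", None)
        store.update_entity(target_ref, params, acting_user=user_ref, now=now, comment=comment)
    else:
        store.delete_entity(target_ref, acting_user=user_ref, now=now)
    return WriteResult(q.action, target_ref.unqualified())


# ----------------------------------------------------------------------
# SPARQL serialization

_PREFIXES = (
    "PREFIX s3db: <{ns}>\n"
    "PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>\n"
)


def to_sparql(q: S3QLQuery, core: CoreModel | None = None,
              base_url: str = "http://localhost/s3db") -> str:
    """Serialize a select to a SPARQL 1.1 SELECT over the exported quads.

    ``base_url`` must match the deployment URL the quads were exported
    from (entity URIs are ``base_url/UID``).  Output is deterministic.
    """
    from .core_model import default_core  # local to avoid cycle at import
    core = core or default_core()
    if q.action != "select":
        raise UnsupportedOperationError(
            f"only select serializes to SPARQL; {q.action!r} is a write operation")
    entity = core.entity(q.entity)
    ns = core.namespace
    var = f"?{entity.name.lower()}"
    type_uri = f"s3db:{entity.name.lower()}"
    prefixes = _PREFIXES.format(ns=ns)
    if entity.name == "Statement":
        rule = q.param("rule_id")
        pred = f"<{base_url}/{rule.uid}>" if isinstance(rule, EntityRef) else "?rule"
        if q.projection == "value":
            select = "?object"
        else:
            select = f"{var} ?subject ?object"
        return (
            f"{prefixes}SELECT {select} WHERE {{\n"
            f"  {var} a {type_uri} .\n"
            f"  GRAPH {var} {{ ?subject {pred} ?object }}\n"
            f"}}"
        )
    lines = [f"  {var} a {type_uri} ."]
    select_vars = [var]
    for key, value in q.params:
        if key == "key":
            continue
        if key in ("id", f"{entity.name.lower()}_id") and isinstance(value, EntityRef):
            lines.append(f'  {var} s3db:id "{value.uid}" .')
        elif isinstance(value, EntityRef):
            lines.append(f"  {var} s3db:{key} <{base_url}/{value.uid}> .")
        else:
            lines.append(f'  {var} s3db:{key} "{value}" .')
    if q.projection:
        pvar = f"?{q.projection}"
        pred = "rdfs:label" if q.projection == "label" else f"s3db:{q.projection}"
        lines.append(f"  {var} {pred} {pvar} .")
        select_vars = [pvar]
    else:
        lines.append(f"  OPTIONAL {{ {var} rdfs:label ?label }}")
        select_vars.append("?label")
    return f"{prefixes}SELECT {' '.join(select_vars)} WHERE {{\n" + "\n".join(lines) + "\n}"


_PATTERN_RE = re.compile(
    r"^\s*\?(?P<s>\w+)\s+(?P<p>\S+)\s+(?P<o>\?\w+|\S+)\s*\.?\s*$")


def sparql_to_s3ql(pattern: str, core: CoreModel | None = None,
                   projected: list[str] | None = None) -> S3QLQuery:
    """Serialize a single rule-predicate SPARQL pattern to S3QL.

    Supported fragment: one triple pattern whose predicate is a rule UID
    (``?Patient :R390 ?cancerType`` -> ``select(S|R390)``).  Joins of
    several patterns, non-rule predicates and non-variable subjects fall
    outside the fragment.
    """
    from .core_model import default_core
    core = core or default_core()
    stripped = pattern.strip().rstrip(".").strip()
    if re.search(r"\.\s*\?", pattern) or "\n" in stripped or re.search(r"\}\s*\{", pattern):
        raise UnsupportedFragmentError(
            "only a single triple pattern with a rule-UID predicate is supported; "
            "joins of several patterns are outside the fragment")
    m = _PATTERN_RE.match(pattern)
    if not m:
        raise UnsupportedFragmentError(
            f"cannot interpret pattern {pattern!r}: supported fragment is "
            "'?subject <ruleUID> ?object'")
    pred = m.group("p").strip("<>").rstrip(">")
    tail = pred.rsplit("/", 1)[-1].rsplit(":", 1)[-1].lstrip(":")
    ref_m = re.match(r"^([A-Z])(\d+)$", tail)
    rule_entity = core.entity("Rule") if any(e.name == "Rule" for e in core.entities) else None
    if not ref_m or rule_entity is None or ref_m.group(1) != rule_entity.letter:
        raise UnsupportedFragmentError(
            f"predicate {pred!r} is not a rule UID; supported fragment requires "
            f"a {rule_entity.letter if rule_entity else 'R'}<number> predicate")
    rule = EntityRef(ref_m.group(1), int(ref_m.group(2)))
    projection = None
    obj = m.group("o")
    if projected and obj.startswith("?") and projected == [obj[1:]]:
        projection = "value"
    return S3QLQuery("select", "Statement", projection, (("rule_id", rule),))
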