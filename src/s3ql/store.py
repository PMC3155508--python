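"""Typed named-graph quad store.

Every entity instance is a named graph: the graph name is the instance
URI, the graph's *type* is its entity type, and five contextual
descriptors (id, label, description, creator, created) annotate the
graph name in the default graph.  ``id``, ``created`` and ``creator``
are assigned by the store at insert time and immutable thereafter;
``label`` and ``description`` belong to the submitter.

Domain and instantiation are separated: a *rule* graph holds one domain
triple ``[SubjectCollection verb Object]`` and the rule's graph name is
then used as the **predicate** of every *statement* graph instantiating
it (``[item :R12 value]``).  Renaming a rule's verb therefore never
touches the statements that use it.

Deletion is soft: entities are marked deprecated, leaving no dangling
references, and vanish from default query results.  Export/import is
lossless through TriG or N-Quads (rdflib); Turtle export of the merged
triples is offered as a lossy convenience.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping
from urllib.parse import quote

from rdflib import Dataset, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import DCTERMS, XSD

from .clock import Clock, isoformat
from .core_model import CoreModel, EntityRef, EntityType, default_core, looks_like_ref
from .errors import (
    DependencyError,
    DomainViolationError,
    ImmutableAttributeError,
    NotFoundError,
    ParseError,
    TypeMismatchError,
    ValidationError,
)
from .permissions import (
    OPERATOR_NS,
    PermissionAssignment,
    PermissionState,
    TransitionMatrix,
    parse_state,
    propagate,
)

SYSTEM_ATTRS = ("id", "creator", "created")


@dataclass
class EntityRecord:
    """In-memory image of one typed named graph."""

    ref: EntityRef
    entity: EntityType
    attrs: dict
    creator: EntityRef | None
    created: str
    deprecated: bool = False
    changes: list = field(default_factory=list)  # (timestamp, actor, comment)

    @property
    def uid(self) -> str:
        return self.ref.uid

    @property
    def label(self):
        return self.attrs.get("label")

    def row(self) -> dict:
        row = {"id": self.uid, "creator": str(self.creator) if self.creator else None,
               "created": self.created}
        row.update({k: (str(v) if isinstance(v, EntityRef) else v) for k, v in self.attrs.items()})
        return row


class Store:
    """One deployment's content: entity graphs plus permission triples.

    The store itself enforces structural rules (required parents,
    domain/range of statements, immutability of system attributes) but
    not permissions — permission gating lives in
    :func:`s3ql.query.execute`, which consults this store's assignment
    table.
    """

    def __init__(self, core: CoreModel | None = None, deployment_number: int = 1,
                 url: str = "http://localhost/s3db", label: str = "deployment",
                 clock: Clock | None = None):
        self.core = core or default_core()
        self.url = url.rstrip("/")
        self.clock = clock or Clock()
        self.records: dict[str, EntityRecord] = {}
        self._counters: dict[str, int] = defaultdict(int)
        # one assigned state per (user, target): re-assignment replaces
        self.permissions: dict[tuple[str, str], PermissionState] = {}
        self.log: list[str] = []
        self.deployment: EntityRef | None = None
        if self.core.deployment_letter:
            self.deployment = self.insert_entity(
                "Deployment", {"label": label, "url": self.url}, number=deployment_number)
            # the bootstrap graph is self-created until an admin takes over
            self.records[self.deployment.uid].creator = self.deployment

    # ------------------------------------------------------------------
    # identifiers
    def uri(self, ref: EntityRef | str) -> URIRef:
        uid = ref.uid if isinstance(ref, EntityRef) else EntityRef.parse(ref).uid
        return URIRef(f"{self.url}/{uid}")

    def _mint(self, letter: str, number: int | None) -> EntityRef:
        if number is None:
            self._counters[letter] += 1
            number = self._counters[letter]
        else:
            self._counters[letter] = max(self._counters[letter], number)
        ref = EntityRef(letter, number)
        if ref.uid in self.records:
            raise ValidationError(f"UID {ref.uid} already exists")
        return ref

    def _log(self, actor, action: str, ref, now) -> None:
        who = str(actor) if actor else "system"
        self.log.append(f"{now}\t{who}\t{action}\t{ref}")

    # ------------------------------------------------------------------
    # lookup
    def get(self, ref: EntityRef | str, include_deprecated: bool = False) -> EntityRecord:
        uid = ref.uid if isinstance(ref, EntityRef) else EntityRef.parse(ref).uid
        rec = self.records.get(uid)
        if rec is None or (rec.deprecated and not include_deprecated):
            raise NotFoundError(f"entity {uid} not found in deployment "
                                f"{self.deployment.uid if self.deployment else '?'}")
        return rec

    def exists(self, ref) -> bool:
        try:
            self.get(ref)
            return True
        except NotFoundError:
            return False

    def select(self, entity: EntityType | str, filters: Mapping | None = None,
               include_deprecated: bool = False) -> list[EntityRecord]:
        entity = self.core.entity(entity)
        self_key = f"{entity.name.lower()}_id"
        out = []
        for rec in self.records.values():
            if rec.entity.name != entity.name:
                continue
            if rec.deprecated and not include_deprecated:
                continue
            ok = True
            for key, want in (filters or {}).items():
                want_s = str(want)
                if key in ("id", self_key) and not (
                        entity.name == "Deployment" and key == "deployment_id"
                        and "deployment_id" in rec.attrs):
                    have = rec.uid
                elif key == "creator":
                    have = str(rec.creator) if rec.creator else None
                else:
                    got = rec.attrs.get(key)
                    have = str(got) if isinstance(got, EntityRef) else got
                if have is None or str(have) != want_s:
                    # a Deployment's own uid also answers deployment_id
                    if key == "deployment_id" and entity.name == "Deployment" and rec.uid == want_s:
                        continue
                    ok = False
                    break
            if ok:
                out.append(rec)
        return sorted(out, key=lambda r: (r.ref.letter, r.ref.number))

    # ------------------------------------------------------------------
    # writes
    def insert_entity(self, kind: EntityType | str, params: Mapping, acting_user: EntityRef | None = None,
                      now=None, number: int | None = None) -> EntityRef:
        """Insert a new entity instance; returns the freshly minted ref.

        Validates attribute names, required parent references and parent
        types *before* mutating, so a failed insert adds nothing.
        """
        entity = self.core.entity(kind)
        attrs: dict = {}
        for key, value in params.items():
            if key in SYSTEM_ATTRS:
                raise ImmutableAttributeError(
                    f"attribute {key!r} is system-assigned and cannot be supplied")
            if key == "deployment_id" and entity.name == "Deployment":
                continue  # consumed by the caller as an explicit UID
            if key not in entity.attribute_names:
                raise ValidationError(
                    f"unknown attribute {key!r} for entity {entity.name} "
                    f"(valid: {', '.join(sorted(entity.submitter_attributes))})")
            attrs[key] = value
        # required parents per the core model's relationships
        parent_checks = []
        for rel in self.core.relationships_into(entity):
            if not rel.attribute:
                continue
            value = attrs.get(rel.attribute)
            if value is None:
                if rel.required:
                    raise DependencyError(
                        f"inserting a {entity.name} requires {rel.attribute!r} "
                        f"({rel.name} relationship: {rel.meaning})", relationship=rel.name)
                continue
            if isinstance(value, str) and looks_like_ref(value):
                value = EntityRef.parse(value)
            if isinstance(value, EntityRef):
                attrs[rel.attribute] = value
                parent_checks.append((rel, value))
        for rel, parent_ref in parent_checks:
            if parent_ref.qualifiers:
                continue  # cross-deployment parents resolve elsewhere
            parent = self.get(parent_ref)
            expected = self.core.entity(rel.from_entity)
            if parent.entity.name != expected.name and not (
                    rel.attribute in ("object", "value")):  # range attrs may point elsewhere
                raise TypeMismatchError(
                    f"{rel.attribute!r} of a {entity.name} must reference a "
                    f"{expected.name}, got {parent.entity.name} {parent_ref.uid}")
        ref = self._mint(entity.letter, number)
        now = now or self.clock.now()
        created = now if isinstance(now, str) else isoformat(now)
        creator = acting_user if acting_user is not None else self.deployment
        self.records[ref.uid] = EntityRecord(ref, entity, attrs, creator, created)
        self._log(acting_user, f"insert {entity.name}", ref.uid, created)
        return ref

    def add_rule(self, subject: EntityRef, verb: str, obj, acting_user=None, now=None,
                 number: int | None = None, label: str | None = None) -> EntityRef:
        """Create a domain rule ``[subject verb obj]`` as a rule-typed graph.

        ``subject`` must be a Collection; ``obj`` is a Collection ref or
        a literal-class name.  The verb remains editable without touching
        the statements instantiating the rule.
        """
        subj_rec = self.get(subject)
        if subj_rec.entity.name != "Collection":
            raise TypeMismatchError(
                f"rule subject must be a Collection, got {subj_rec.entity.name} {subject}")
        params = {"subject_id": subject, "verb": verb, "object": obj,
                  "label": label or verb}
        return self.insert_entity("Rule", params, acting_user, now, number)

    def add_statement(self, item: EntityRef, rule: EntityRef, value, acting_user=None,
                      now=None, number: int | None = None) -> EntityRef:
        """Instantiate ``rule`` on ``item``: the statement triple's predicate
        is the rule's graph name."""
        item_rec = self.get(item)
        if item_rec.entity.name != "Item":
            raise TypeMismatchError(f"statement subject must be an Item, got {item_rec.entity.name}")
        rule_rec = self.get(rule)
        if rule_rec.entity.name != "Rule":
            raise TypeMismatchError(f"statement predicate must be a Rule, got {rule_rec.entity.name}")
        domain = rule_rec.attrs.get("subject_id")
        if domain is not None and str(item_rec.attrs.get("collection_id")) != str(domain):
            raise DomainViolationError(
                f"item {item} belongs to collection {item_rec.attrs.get('collection_id')} "
                f"but rule {rule} has domain {domain}")
        if isinstance(value, str) and looks_like_ref(value):
            value = EntityRef.parse(value)
        if isinstance(value, EntityRef) and not value.qualifiers:
            vrec = self.get(value)
            rng = rule_rec.attrs.get("object")
            if isinstance(rng, EntityRef) and vrec.entity.name == "Item":
                if str(vrec.attrs.get("collection_id")) != str(rng):
                    raise DomainViolationError(
                        f"value item {value} is not in the rule's object collection {rng}")
        return self.insert_entity("Statement", {"item_id": item, "rule_id": rule, "value": value},
                                  acting_user, now, number)

    def update_entity(self, ref: EntityRef, params: Mapping, acting_user=None, now=None,
                      comment: str | None = None) -> EntityRecord:
        """Rewrite submitter-assigned attributes; records modifier and an
        optional change comment as contextual descriptors."""
        rec = self.get(ref)
        for key in params:
            if key in SYSTEM_ATTRS:
                raise ImmutableAttributeError(f"attribute {key!r} is system-assigned and immutable")
            if key not in rec.entity.attribute_names:
                raise ValidationError(f"unknown attribute {key!r} for entity {rec.entity.name}")
        now = now or self.clock.now()
        ts = now if isinstance(now, str) else isoformat(now)
        for key, value in params.items():
            if isinstance(value, str) and looks_like_ref(value) and key.endswith("_id"):
                value = EntityRef.parse(value)
            rec.attrs[key] = value
        rec.changes.append((ts, str(acting_user) if acting_user else "system", comment or ""))
        self._log(acting_user, "update", rec.uid, ts)
        return rec

    def delete_entity(self, ref: EntityRef, acting_user=None, now=None) -> EntityRecord:
        """Soft delete: mark deprecated; the graph survives for export with
        ``include_deprecated`` but leaves default query results."""
        rec = self.get(ref)
        rec.deprecated = True
        now = now or self.clock.now()
        ts = now if isinstance(now, str) else isoformat(now)
        rec.changes.append((ts, str(acting_user) if acting_user else "system", "deprecated"))
        self._log(acting_user, "delete", rec.uid, ts)
        return rec

    # ------------------------------------------------------------------
    # permissions
    def assign_permission(self, user: EntityRef | str, target: EntityRef | str,
                          state: PermissionState | str) -> PermissionAssignment:
        if isinstance(state, str):
            state = parse_state(state)
        user_ref = user if isinstance(user, EntityRef) else EntityRef.parse(user)
        target_ref = target if isinstance(target, EntityRef) else EntityRef.parse(target)
        self.permissions[(str(user_ref), target_ref.uid)] = state
        return PermissionAssignment(user_ref, target_ref, state)

    def remove_permission(self, user, target) -> None:
        self.permissions.pop((str(user), EntityRef.parse(str(target)).uid), None)

    def assignments_for(self, user: EntityRef | str) -> dict[str, PermissionState]:
        key = str(user)
        return {target: st for (u, target), st in self.permissions.items() if u == key}

    def effective_permissions(self, user: EntityRef | str,
                              memory_length: int | None = None) -> dict[str, PermissionState]:
        matrix = TransitionMatrix.from_store(self, memory_length)
        return propagate(self.assignments_for(user), matrix)

    # ------------------------------------------------------------------
    # transition-matrix instantiation
    def instance_nodes(self) -> list[str]:
        return [uid for uid, rec in self.records.items() if not rec.deprecated]

    def instance_edges(self) -> list[tuple[str, str]]:
        """Parent -> child edges instantiated from the core relationships."""
        edges = []
        dep_uid = self.deployment.uid if self.deployment else None
        for rel in self.core.relationships:
            to_name = rel.to_entity
            for rec in self.records.values():
                if rec.deprecated or rec.entity.name != to_name:
                    continue
                if rel.attribute:
                    parent = rec.attrs.get(rel.attribute)
                    if isinstance(parent, EntityRef) and not parent.qualifiers \
                            and parent.uid in self.records and parent.uid != rec.uid:
                        if self.records[parent.uid].entity.name == rel.from_entity:
                            edges.append((parent.uid, rec.uid))
                elif rel.from_entity == "Deployment" and dep_uid and rec.uid != dep_uid:
                    edges.append((dep_uid, rec.uid))
        return edges

    def transition_matrix(self, memory_length: int | None = None) -> TransitionMatrix:
        return TransitionMatrix.from_store(self, memory_length)

    # ------------------------------------------------------------------
    # RDF export / import
    def _namespaces(self):
        ns = Namespace(self.core.namespace)
        op = Namespace(OPERATOR_NS)
        return ns, op

    def _attr_node(self, value):
        if isinstance(value, EntityRef):
            return self.uri(value)
        return Literal(value)

    def build_dataset(self, include_deprecated: bool = False) -> Dataset:
        ns, op = self._namespaces()
        ds = Dataset()
        ds.bind("s3db", ns)
        ds.bind("op", op)
        ds.bind("dcterms", DCTERMS)
        ds.bind("rdfs", RDFS)
        for rec in self.records.values():
            if rec.deprecated and not include_deprecated:
                continue
            uri = self.uri(rec.ref)
            ds.add((uri, RDF.type, ns[rec.entity.name.lower()]))
            ds.add((uri, ns.id, Literal(rec.uid)))
            ds.add((uri, DCTERMS.created, Literal(rec.created, datatype=XSD.dateTime)))
            if rec.creator is not None:
                ds.add((uri, DCTERMS.creator, self.uri(rec.creator)))
            for key, value in sorted(rec.attrs.items()):
                if value is None:
                    continue
                if key == "label":
                    ds.add((uri, RDFS.label, Literal(value)))
                elif key == "description":
                    ds.add((uri, DCTERMS.description, Literal(value)))
                else:
                    ds.add((uri, ns[key], self._attr_node(value)))
            if rec.deprecated:
                ds.add((uri, ns.deprecated, Literal(True)))
            for ts, actor, comment in rec.changes:
                ds.add((uri, ns.changeNote, Literal(f"{ts} {actor}: {comment}")))
            graph = ds.graph(uri)
            if rec.entity.name == "Rule":
                subj = rec.attrs.get("subject_id")
                if isinstance(subj, EntityRef):
                    verb_uri = URIRef(f"{self.url}/{rec.uid}#{quote(str(rec.attrs.get('verb', 'relatedTo')))}")
                    graph.add((self.uri(subj), verb_uri, self._attr_node(rec.attrs.get("object"))))
            elif rec.entity.name == "Statement":
                item, rule = rec.attrs.get("item_id"), rec.attrs.get("rule_id")
                if isinstance(item, EntityRef) and isinstance(rule, EntityRef):
                    graph.add((self.uri(item), self.uri(rule), self._attr_node(rec.attrs.get("value"))))
        if self.permissions:
            pgraph = ds.graph(URIRef(f"{self.url}/permissions"))
            for (user, target), state in self.permissions.items():
                user_uri = self.uri(EntityRef.parse(user))
                pgraph.add((user_uri, op[str(state)], self.uri(target)))
        return ds

    def export_quads(self, format: str = "trig", include_deprecated: bool = False) -> str:
        """Serialize the store as quads (``trig`` or ``nquads``) or as a
        lossy single graph (``turtle``: drops graph names)."""
        ds = self.build_dataset(include_deprecated)
        if format == "turtle":
            merged = Graph()
            for s, p, o, _ in ds.quads((None, None, None, None)):
                merged.add((s, p, o))
            for prefix, uri in ds.namespaces():
                merged.bind(prefix, uri)
            return merged.serialize(format="turtle")
        if format not in ("trig", "nquads"):
            raise ValueError(f"unsupported export format {format!r}")
        return ds.serialize(format=format)

    def canonical_export(self, include_deprecated: bool = True) -> str:
        """Sorted N-Quads — byte-identical for structurally equal stores."""
        lines = self.export_quads("nquads", include_deprecated).splitlines()
        return "\n".join(sorted(line for line in lines if line.strip())) + "\n"

    @classmethod
    def import_quads(cls, text: str, format: str = "trig",
                     core: CoreModel | None = None) -> "Store":
        """Reconstruct a store from a TriG/N-Quads serialization produced
        by :meth:`export_quads`."""
        core = core or default_core()
        ds = Dataset()
        try:
            ds.parse(data=text, format=format)
        except Exception as exc:  # rdflib raises assorted parse errors
            raise ParseError(f"malformed {format} input: {exc}") from exc
        ns, _ = Namespace(core.namespace), Namespace(OPERATOR_NS)
        type_map = {str(Namespace(core.namespace)[e.name.lower()]): e for e in core.entities}
        found = []
        for s, p, o in ds.triples((None, RDF.type, None)):
            ent = type_map.get(str(o))
            if ent is not None:
                found.append((s, ent))
        dep_uri = next((s for s, e in found if e.name == "Deployment"), None)
        url = None
        if dep_uri is not None:
            url = next((str(o) for o in ds.objects(dep_uri, ns.url)), None)
        store = cls.__new__(cls)
        store.core = core
        store.url = (url or "http://localhost/s3db").rstrip("/")
        store.clock = Clock()
        store.records = {}
        store._counters = defaultdict(int)
        store.permissions = {}
        store.log = []
        store.deployment = None
        for s, ent in found:
            uid = next((str(o) for o in ds.objects(s, ns.id)), None)
            if uid is None:
                raise ParseError(f"graph {s} lacks an id descriptor")
            ref = EntityRef.parse(uid)
            created = next((str(o) for o in ds.objects(s, DCTERMS.created)), "")
            creator_uri = next((o for o in ds.objects(s, DCTERMS.creator)), None)
            creator = None
            if creator_uri is not None:
                tail = str(creator_uri).rsplit("/", 1)[-1]
                if looks_like_ref(tail):
                    creator = EntityRef.parse(tail)
            attrs: dict = {}
            for p, o in ds.predicate_objects(s):
                pstr = str(p)
                if p == RDFS.label:
                    attrs["label"] = str(o)
                elif p == DCTERMS.description:
                    attrs["description"] = str(o)
                elif pstr.startswith(str(ns)):
                    key = pstr[len(str(ns)):]
                    if key in ("id", "deprecated", "changeNote"):
                        continue
                    if key in ent.attribute_names:
                        if isinstance(o, URIRef):
                            tail = str(o).rsplit("/", 1)[-1]
                            attrs[key] = EntityRef.parse(tail) if looks_like_ref(tail) else str(o)
                        else:
                            attrs[key] = o.toPython() if o.datatype else str(o)
            deprecated = any(True for _ in ds.objects(s, ns.deprecated))
            changes = []
            for o in ds.objects(s, ns.changeNote):
                note = str(o)
                ts, _, rest = note.partition(" ")
                actor, _, comment = rest.partition(": ")
                changes.append((ts, actor, comment))
            rec = EntityRecord(ref, ent, attrs, creator, created, deprecated, sorted(changes))
            store.records[ref.uid] = rec
            store._counters[ref.letter] = max(store._counters[ref.letter], ref.number)
            if ent.name == "Deployment" and store.deployment is None:
                store.deployment = ref
        perm_graph = ds.graph(URIRef(f"{store.url}/permissions"))
        for s, p, o in perm_graph:
            pstr = str(p)
            if pstr.startswith(OPERATOR_NS):
                state = parse_state(pstr[len(OPERATOR_NS):])
                user = EntityRef.parse(str(s).rsplit("/", 1)[-1])
                target = EntityRef.parse(str(o).rsplit("/", 1)[-1])
                store.permissions[(str(user), target.uid)] = state
        return store
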