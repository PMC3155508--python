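"""Pluggable knowledge-organization core models and the UID scheme.

A *core model* declares the entity types of a knowledge organization
system (KOS), the attributes each type carries, and the directed
relationships between types.  The relationships double as the transition
matrix along which permission states propagate (see
:mod:`s3ql.permissions`).

Two core descriptions are bundled:

``s3db``
    The default: seven entities — Deployment (D), User (U), Project (P),
    Collection (C), Rule (R), Item (I), Statement (S) — five common
    attributes (id, label, description, creator, created) and twelve
    relationships.
``skos``
    A minimal Simple Knowledge Organization System core (Concept,
    Scheme) demonstrating that the query language is not tied to the
    default model.

Entity instances are identified by compact alphanumeric UIDs: the entity
letter followed by a number (``P126``), optionally qualified by one or
more deployment UIDs for cross-deployment reference (``D282:P126``,
``D1016666:D327:R172930`` with a root deployment prepended).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CoreModelError, ParseError

SYSTEM = "system"
SUBMITTER = "submitter"

_BUNDLED = {"s3db", "skos"}

_REF_RE = re.compile(r"^([A-Za-z])(\d+)$")


@dataclass(frozen=True)
class EntityRef:
    """A typed alphanumeric UID, optionally deployment-qualified.

    ``qualifiers`` is the ordered chain of deployment UIDs (as text,
    e.g. ``("D1016666", "D327")``); ``letter`` is the entity letter and
    ``number`` the per-deployment sequence number.
    """

    letter: str
    number: int
    qualifiers: tuple[str, ...] = ()

    @property
    def uid(self) -> str:
        """Unqualified text form, e.g. ``P126``."""
        return f"{self.letter}{self.number}"

    def unqualified(self) -> "EntityRef":
        return EntityRef(self.letter, self.number) if self.qualifiers else self

    def qualified(self, *deployment_uids: str) -> "EntityRef":
        return EntityRef(self.letter, self.number, tuple(deployment_uids) + self.qualifiers)

    def __str__(self) -> str:
        return ":".join(self.qualifiers + (self.uid,))

    @classmethod
    def parse(cls, text: str) -> "EntityRef":
        """Lenient parse (any single entity letter); see
        :func:`parse_entity_ref` for core-model-aware validation."""
        if not text or not isinstance(text, str):
            raise ParseError(f"empty entity reference: {text!r}")
        segments = text.strip().split(":")
        parts = []
        for seg in segments:
            m = _REF_RE.match(seg)
            if not m:
                raise ParseError(
                    f"invalid UID segment {seg!r} in {text!r}: expected an entity "
                    f"letter followed by a number (e.g. P126)"
                )
            parts.append((m.group(1), int(m.group(2))))
        letter, number = parts[-1]
        quals = tuple(f"{l}{n}" for l, n in parts[:-1])
        return cls(letter, number, quals)


def looks_like_ref(text: str) -> bool:
    try:
        EntityRef.parse(text)
        return True
    except ParseError:
        return False


@dataclass(frozen=True)
class EntityType:
    """One entity type of a core model.

    ``attributes`` maps each attribute name to ``"system"`` (assigned by
    the store at write time: id, created, creator) or ``"submitter"``.
    """

    name: str
    letter: str
    attributes: tuple[tuple[str, str], ...]

    @property
    def attribute_names(self) -> set[str]:
        return {a for a, _ in self.attributes}

    @property
    def system_attributes(self) -> set[str]:
        return {a for a, kind in self.attributes if kind == SYSTEM}

    @property
    def submitter_attributes(self) -> set[str]:
        return {a for a, kind in self.attributes if kind == SUBMITTER}


@dataclass(frozen=True)
class Relationship:
    """A directed dependency between two entity types.

    ``attribute`` names the child-side attribute carrying the parent
    reference (``None`` for structural relationships such as a user
    belonging to its deployment); ``required`` marks attributes that
    must be supplied at insert time.
    """

    name: str
    from_entity: str
    to_entity: str
    attribute: str | None = None
    required: bool = False
    meaning: str = ""


@dataclass
class CoreModel:
    name: str
    namespace: str
    entities: tuple[EntityType, ...]
    relationships: tuple[Relationship, ...] = ()
    _by_letter: dict = field(init=False, repr=False, default_factory=dict)
    _by_name: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        for e in self.entities:
            self._by_letter[e.letter] = e
            self._by_name[e.name.lower()] = e

    # -- lookup ---------------------------------------------------------
    @property
    def letters(self) -> list[str]:
        return [e.letter for e in self.entities]

    def entity(self, key: str) -> EntityType:
        """Look up an entity type by letter or (case-insensitive) name."""
        if isinstance(key, EntityType):
            return key
        if len(key) == 1 and key in self._by_letter:
            return self._by_letter[key]
        ent = self._by_name.get(key.lower())
        if ent is None:
            raise CoreModelError(
                f"unknown entity {key!r} in core model {self.name!r}; "
                f"valid letters: {', '.join(sorted(self._by_letter))}"
            )
        return ent

    def has_letter(self, letter: str) -> bool:
        return letter in self._by_letter

    @property
    def deployment_letter(self) -> str | None:
        ent = self._by_name.get("deployment")
        return ent.letter if ent else None

    def relationships_into(self, entity: EntityType) -> list[Relationship]:
        return [r for r in self.relationships if r.to_entity == entity.name]

    def ref_attribute(self, target: EntityType, letter: str) -> str:
        """Attribute name a bare UID of ``letter`` stands for when used as
        a parameter on ``target`` (e.g. a bare ``P156`` on a Collection is
        its ``project_id``; shorthand for ``project_id=156``)."""
        parent = self._by_letter.get(letter)
        if parent is not None:
            for rel in self.relationships_into(target):
                if rel.from_entity == parent.name and rel.attribute:
                    return rel.attribute
        if parent is not None and parent.name == target.name:
            return f"{target.name.lower()}_id"
        if parent is not None:
            return f"{parent.name.lower()}_id"
        return f"{letter.lower()}_id"

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "namespace": self.namespace,
            "entities": [
                {"name": e.name, "letter": e.letter, "attributes": dict(e.attributes)}
                for e in self.entities
            ],
            "relationships": [
                {
                    "name": r.name,
                    "from": r.from_entity,
                    "to": r.to_entity,
                    "attribute": r.attribute,
                    "required": r.required,
                    "meaning": r.meaning,
                }
                for r in self.relationships
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _validate(doc: dict) -> CoreModel:
    if not isinstance(doc, dict):
        raise CoreModelError("core-model document must be a JSON object")
    entities_raw = doc.get("entities")
    if not entities_raw:
        raise CoreModelError("core-model document declares no entities")
    entities = []
    seen_letters: set[str] = set()
    names: set[str] = set()
    for e in entities_raw:
        try:
            name, letter = e["name"], e["letter"]
        except (TypeError, KeyError) as exc:
            raise CoreModelError(f"entity missing field {exc} in {e!r}") from None
        if len(letter) != 1 or not letter.isupper():
            raise CoreModelError(f"entity {name!r}: letter must be one uppercase character, got {letter!r}")
        if letter in seen_letters:
            raise CoreModelError(f"entity {name!r}: duplicate letter {letter!r}")
        seen_letters.add(letter)
        names.add(name)
        attrs = e.get("attributes", {})
        for a, kind in attrs.items():
            if kind not in (SYSTEM, SUBMITTER):
                raise CoreModelError(f"entity {name!r}: attribute {a!r} kind must be 'system' or 'submitter'")
        entities.append(EntityType(name, letter, tuple(sorted(attrs.items()))))
    rels = []
    seen_rel: set[str] = set()
    for r in doc.get("relationships", []):
        rname = r.get("name")
        if rname in seen_rel:
            raise CoreModelError(f"duplicate relationship name {rname!r}")
        seen_rel.add(rname)
        for end in ("from", "to"):
            if r.get(end) not in names:
                raise CoreModelError(
                    f"relationship {rname!r}: endpoint {r.get(end)!r} is not a declared entity"
                )
        rels.append(
            Relationship(
                rname, r["from"], r["to"], r.get("attribute"), bool(r.get("required", False)), r.get("meaning", "")
            )
        )
    return CoreModel(doc.get("name", "custom"), doc.get("namespace", "http://example.org/core#"),
                     tuple(entities), tuple(rels))


def load_core_model(source: str | Path | Mapping | None = None) -> CoreModel:
    """Load and validate a core-model description.

    ``source`` may be a bundled core name (``"s3db"``/``"skos"``), a path
    to a JSON description file, an already-parsed mapping, or ``None``
    (the default s3db core).
    """
    if source is None:
        source = "s3db"
    if isinstance(source, Mapping):
        return _validate(dict(source))
    if isinstance(source, str) and source in _BUNDLED:
        text = resources.files("s3ql").joinpath("cores", f"{source}.json").read_text()
        return _validate(json.loads(text))
    path = Path(source)
    try:
        text = path.read_text()
    except OSError as exc:
        raise CoreModelError(f"cannot read core-model file {source!r}: {exc}") from exc
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CoreModelError(f"malformed core-model document {source!r}: {exc}") from exc
    return _validate(doc)


def default_core() -> CoreModel:
    return load_core_model("s3db")


def parse_entity_ref(text: str, core: CoreModel) -> EntityRef:
    """Parse a (possibly deployment-qualified) UID, validated against ``core``.

    Qualifier segments must carry the core's deployment letter; the final
    segment's letter must name a declared entity.
    """
    ref = EntityRef.parse(text)
    if not core.has_letter(ref.letter):
        raise ParseError(
            f"unknown entity letter {ref.letter!r} in {text!r}; valid letters in "
            f"core {core.name!r}: {', '.join(sorted(core.letters))}"
        )
    dep = core.deployment_letter
    for q in ref.qualifiers:
        if dep is None or not q.startswith(dep):
            raise ParseError(
                f"qualifier {q!r} in {text!r} is not a deployment UID"
                + (f" (expected letter {dep!r})" if dep else " (core has no deployment entity)")
            )
    return ref


def common_attributes(core: CoreModel) -> set[str]:
    """Attributes shared by every entity type of ``core`` (the s3db core's
    five contextual descriptors: id, label, description, creator, created)."""
    sets = [e.attribute_names for e in core.entities]
    return set.intersection(*sets) if sets else set()
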