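"""The S3QL query language: compact and XML flavours, plus the translator.

One management operation is written either compactly as::

    action(E | E.a = value, ...)

where the ``|`` reads "given that", ``E`` is an entity of the active
core model (single letter or full name), an optional ``E.a`` before the
``|`` projects one attribute, and parameters are either ``attr = value``
pairs or bare alphanumeric UIDs (``P156`` is shorthand for
``project_id = 156``); or as the equivalent XML::

    <S3QL>
      <insert>project</insert>
      <where>
        <label>Test</label>
      </where>
    </S3QL>

The two forms carry the same information and interconvert losslessly:
``parse_xml(to_xml(q)) == q`` and ``parse_compact(to_compact(q)) == q``.
Whitespace around ``|``, ``=`` and ``,`` is insignificant; actions and
entity names are case-insensitive on input and canonical lowercase on
output; attribute names are case-sensitive (they mirror RDF terms such
as ``prefLabel``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from lxml import etree

from .core_model import CoreModel, EntityRef, default_core, looks_like_ref
from .errors import ParseError, ValidationError

ACTIONS = ("select", "insert", "update", "delete")

_COMPACT_RE = re.compile(
    r"^\s*(?P<action>[A-Za-z_]\w*)\s*\(\s*(?P<entity>[A-Za-z_]\w*)"
    r"(?:\s*\.\s*(?P<proj>\w+))?\s*(?:\|(?P<params>.*))?\)\s*$",
    re.S,
)

#: Parameter keys whose values are entity references.
REF_KEYS = {"user", "entity"}


@dataclass(frozen=True)
class S3QLQuery:
    """Parsed form of one S3QL operation."""

    action: str
    entity: str  # canonical entity name, e.g. "Project"
    projection: str | None = None
    params: tuple[tuple[str, object], ...] = ()

    def param(self, key: str, default=None):
        for k, v in self.params:
            if k == key:
                return v
        return default

    def without_param(self, key: str) -> "S3QLQuery":
        return S3QLQuery(self.action, self.entity, self.projection,
                         tuple((k, v) for k, v in self.params if k != key))

    def replace_param(self, key: str, value) -> "S3QLQuery":
        return S3QLQuery(self.action, self.entity, self.projection,
                         tuple((k, value if k == key else v) for k, v in self.params))


def _is_ref_key(key: str) -> bool:
    return key in REF_KEYS or key.endswith("_id")


def _coerce_value(key: str, value: str, core: CoreModel):
    """Bare UIDs and ``project_id = 156``-style numerics become EntityRefs."""
    if not isinstance(value, str) or not _is_ref_key(key):
        return value
    if looks_like_ref(value):
        ref = EntityRef.parse(value)
        if core.has_letter(ref.letter):
            return ref
    if value.isdigit() and key.endswith("_id"):
        name = key[:-3]
        try:
            ent = core.entity(name)
            return EntityRef(ent.letter, int(value))
        except Exception:
            return value
    return value


def _check_action(action: str) -> str:
    action = action.lower()
    if action not in ACTIONS:
        raise ParseError(f"unknown action {action!r}; the four S3QL operations are "
                         f"{', '.join(ACTIONS)}")
    return action


def parse_compact(text: str, core: CoreModel | None = None) -> S3QLQuery:
    """Parse the compact ``action(E | E.a = value, ...)`` notation."""
    core = core or default_core()
    if not text or not text.strip():
        raise ParseError("empty query")
    m = _COMPACT_RE.match(text)
    if not m:
        raise ParseError(f"cannot parse compact query {text!r}: expected "
                         f"action(E | params)")
    action = _check_action(m.group("action"))
    entity = core.entity(m.group("entity"))
    projection = m.group("proj")
    params: list[tuple[str, object]] = []
    raw = (m.group("params") or "").strip()
    bare_refs: list[tuple[int, EntityRef]] = []
    if raw:
        for part in raw.split(","):
            part = part.strip()
            if not part:
                continue
            if "=" in part:
                key, _, value = part.partition("=")
                key, value = key.strip(), value.strip()
                params.append((key, _coerce_value(key, value, core)))
            else:
                if not looks_like_ref(part):
                    raise ParseError(f"cannot parse parameter {part!r} in {text!r}")
                ref = EntityRef.parse(part)
                if not core.has_letter(ref.letter):
                    raise ValidationError(
                        f"unknown entity letter {ref.letter!r} in parameter {part!r} "
                        f"under core model {core.name!r}")
                bare_refs.append((len(params), ref))
                params.append((None, ref))  # key resolved below
    # resolve bare-ref keys: permission-assignment form insert(U|U1,P157,...)
    has_level = any(k == "permission_level" for k, _ in params)
    if entity.name == "User" and has_level and bare_refs:
        for i, ref in bare_refs:
            key = "user" if ref.letter == entity.letter else "entity"
            params[i] = (key, ref)
    else:
        for i, ref in bare_refs:
            params[i] = (core.ref_attribute(entity, ref.letter), ref)
    q = S3QLQuery(action, entity.name, projection, tuple(params))
    _check_projection(q, core)
    return q


def _check_projection(q: S3QLQuery, core: CoreModel) -> None:
    if q.projection is None:
        return
    ent = core.entity(q.entity)
    if q.projection not in ent.attribute_names:
        raise ValidationError(
            f"projection {q.projection!r} is not an attribute of {ent.name} "
            f"in core model {core.name!r}")


def parse_xml(text: str | bytes, core: CoreModel | None = None) -> S3QLQuery:
    """Parse the XML flavour: ``<S3QL><action>entity</action><where>...</where></S3QL>``."""
    core = core or default_core()
    try:
        root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if root.tag != "S3QL":
        raise ParseError(f"root element must be <S3QL>, got <{root.tag}>")
    op_el = None
    where_el = None
    for child in root:
        tag = child.tag.lower() if isinstance(child.tag, str) else ""
        if tag in ACTIONS:
            op_el = child
        elif tag == "where":
            where_el = child
    if op_el is None:
        raise ParseError("no operation element (<select>/<insert>/<update>/<delete>) "
                         "inside <S3QL>: the query does not follow the syntax diagram")
    action = _check_action(op_el.tag)
    target = (op_el.text or "").strip()
    if not target:
        raise ParseError(f"operation element <{op_el.tag}> names no target entity")
    projection = None
    if "." in target:
        target, projection = target.split(".", 1)
    entity = core.entity(target)
    params: list[tuple[str, object]] = []
    if where_el is not None:
        for p in where_el:
            if not isinstance(p.tag, str):
                continue
            value = (p.text or "").strip()
            params.append((p.tag, _coerce_value(p.tag, value, core)))
    q = S3QLQuery(action, entity.name, projection, tuple(params))
    _check_projection(q, core)
    return q


def to_xml(q: S3QLQuery, core: CoreModel | None = None) -> str:
    """Canonical XML rendering (two-space indent, lowercase entity name)."""
    core = core or default_core()
    entity = core.entity(q.entity)
    target = entity.name.lower()
    if q.projection:
        target += f".{q.projection}"
    lines = ["<S3QL>", f"  <{q.action}>{target}</{q.action}>"]
    if q.params:
        lines.append("  <where>")
        for key, value in q.params:
            el = etree.Element(key)
            el.text = str(value)
            lines.append("    " + etree.tostring(el, encoding="unicode"))
        lines.append("  </where>")
    lines.append("</S3QL>")
    return "\n".join(lines)


def to_compact(q: S3QLQuery, core: CoreModel | None = None) -> str:
    """Canonical compact rendering; bare UIDs for entity-ref parameters."""
    core = core or default_core()
    entity = core.entity(q.entity)
    head = entity.letter
    if q.projection:
        head += f".{q.projection}"
    parts = []
    for key, value in q.params:
        if isinstance(value, EntityRef) and _is_ref_key(key):
            parts.append(str(value))
        else:
            parts.append(f"{key}={value}")
    if parts:
        return f"{q.action}({head}|{','.join(parts)})"
    return f"{q.action}({head})"


def translate(text: str, core: CoreModel | None = None, to: str = "auto") -> str:
    """The translator: convert one query between compact and XML flavours.

    ``to`` is ``"xml"``, ``"compact"`` or ``"auto"`` (flip whichever
    flavour came in).
    """
    core = core or default_core()
    is_xml = text.lstrip().startswith("<")
    q = parse_xml(text, core) if is_xml else parse_compact(text, core)
    if to == "auto":
        to = "compact" if is_xml else "xml"
    if to == "xml":
        return to_xml(q, core)
    if to == "compact":
        return to_compact(q, core)
    raise ValueError(f"unknown target flavour {to!r}")


def validate(q: S3QLQuery, core: CoreModel | None = None) -> list[str]:
    """Check a query against a core model; returns a list of violations
    (empty means valid)."""
    core = core or default_core()
    violations = []
    if q.action not in ACTIONS:
        violations.append(f"unknown action {q.action!r}")
    try:
        entity = core.entity(q.entity)
    except Exception:
        violations.append(f"unknown entity {q.entity!r} in core model {core.name!r}")
        return violations
    valid_attrs = set(entity.attribute_names) | {"id"}
    # attributes reachable through a relationship (e.g. a parent's key)
    for rel in core.relationships:
        if rel.attribute and entity.name in (rel.from_entity, rel.to_entity):
            valid_attrs.add(rel.attribute)
    if entity.name == "User":
        valid_attrs |= {"permission_level", "user", "entity", "key"}
    valid_attrs.add(f"{entity.name.lower()}_id")
    for key, value in q.params:
        if key not in valid_attrs and not (isinstance(value, EntityRef)):
            violations.append(
                f"{key!r} is not an attribute of {entity.name} (or of a related "
                f"entity) in core model {core.name!r}")
    if q.projection and q.projection not in entity.attribute_names:
        violations.append(f"projection {q.projection!r} invalid for {entity.name}")
    return violations
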