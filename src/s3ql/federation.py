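"""Distributed identifier dereferencing across simulated deployments.

Each deployment is a full store bound to a URL; a *root* deployment
keeps a registry mapping deployment UIDs to URLs, populated with
ordinary S3QL inserts and queried with ``select(D.url|D<n>)``.  A
qualified UID such as ``D282:P126`` resolves root-first: look the
deployment up at the root (subject to a local cache with a 24-hour
TTL), then address the entity at the returned URL.  Recursive
qualification (``D1016666:D327:R172930``) resolves the foreign root
first, then the deployment within it.

Federated selects re-issue the query at the holding deployment with the
qualifier stripped; the holder validates the requesting user against
the user's *home* deployment (``select(U.id|U<n>)`` with the surrogate
token provided) and applies its own permission gating before returning
rows.  Deployments live in one process behind a :class:`Network`
transport abstraction; tokens are opaque random strings bound
server-side to (user, expiry).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .clock import Clock
from .core_model import CoreModel, EntityRef
from .errors import (
    AuthenticationError,
    ConflictError,
    CycleError,
    NotFoundError,
    ResolutionError,
    TokenExpiredError,
    ValidationError,
)
from .language import S3QLQuery, parse_compact
from .query import ResultSet, execute
from .store import Store

#: Default local cache time-to-live for dereferenced deployment URLs.
CACHE_TTL_HOURS = 24


@dataclass(frozen=True)
class Credential:
    """Surrogate token coupled with the user's (possibly qualified) URI."""

    user: EntityRef
    token: str
    issued: datetime
    ttl: float  # seconds


@dataclass
class DeploymentRecord:
    ref: EntityRef
    url: str
    title: str = ""
    description: str = ""


class Network:
    """In-process transport: URL -> deployment instance."""

    def __init__(self):
        self._by_url: dict[str, "Deployment"] = {}

    def add(self, deployment: "Deployment") -> None:
        self._by_url[deployment.url] = deployment

    def by_url(self, url: str) -> "Deployment":
        dep = self._by_url.get(url.rstrip("/"))
        if dep is None:
            raise ResolutionError(f"no deployment reachable at {url!r}")
        return dep


class Deployment:
    """One deployment: a store plus resolver, registry and token service."""

    def __init__(self, number: int, url: str, core: CoreModel | None = None,
                 network: Network | None = None, root_url: str | None = None,
                 clock: Clock | None = None, rng: random.Random | None = None,
                 label: str = "deployment", cache_ttl_hours: float = CACHE_TTL_HOURS):
        self.clock = clock or Clock()
        self.store = Store(core, deployment_number=number, url=url, label=label,
                           clock=self.clock)
        self.url = self.store.url
        self.ref = self.store.deployment
        self.network = network
        self.root_url = root_url
        self.cache_ttl = timedelta(hours=cache_ttl_hours)
        self._cache: dict[tuple[str, str], tuple[str, datetime]] = {}
        self.lookup_count = 0  # registry queries issued to remote roots
        self.rng = rng or random.Random()
        self._tokens: dict[str, tuple[str, datetime]] = {}
        if network is not None:
            network.add(self)

    # ------------------------------------------------------------------
    # registry (when acting as a root)
    def register_deployment(self, ref: EntityRef | str, url: str, title: str = "",
                            description: str = "") -> DeploymentRecord:
        """Record deployment metadata at this root, resolvable thereafter
        via ``select(D.url|D<n>)``."""
        ref = ref if isinstance(ref, EntityRef) else EntityRef.parse(ref)
        if self.store.select("Deployment", {"deployment_id": ref.uid}) and ref.uid != self.ref.uid:
            raise ConflictError(f"deployment {ref.uid} already registered at root {self.ref.uid}")
        if ref.uid == self.ref.uid:
            raise ConflictError(f"{ref.uid} is this root deployment itself")
        self.store.insert_entity("Deployment", {"url": url, "label": title,
                                                "description": description},
                                 number=ref.number)
        return DeploymentRecord(ref, url, title, description)

    def registry_lookup(self, dep_uid: str) -> str:
        """Answer ``select(D.url|D<n>)`` against the local registry."""
        rs = execute(parse_compact(f"select(D.url|{dep_uid})", self.store.core), self.store)
        if not rs.rows or not rs.rows[0].get("url"):
            raise ResolutionError(f"deployment {dep_uid} unknown at root {self.ref.uid}")
        return rs.rows[0]["url"]

    # ------------------------------------------------------------------
    # dereferencing
    def _lookup(self, dep_uid: str, registry_url: str, now: datetime) -> str:
        """Dereference one deployment UID at a registry, through the cache."""
        key = (registry_url, dep_uid)
        hit = self._cache.get(key)
        if hit is not None and now - hit[1] < self.cache_ttl:
            return hit[0]
        if registry_url == self.url:
            url = self.registry_lookup(dep_uid)
        else:
            if self.network is None:
                raise ResolutionError("no network transport configured")
            self.lookup_count += 1
            url = self.network.by_url(registry_url).registry_lookup(dep_uid)
        self._cache[key] = (url, now)
        return url

    def resolve(self, ref: EntityRef | str, now: datetime | None = None) -> tuple[str, str]:
        """Dereference a (possibly qualified) UID to (deployment URL, entity URI).

        Unqualified UIDs are local; a single qualifier is looked up at
        this deployment's root; recursive qualification resolves the
        outer root first, then the inner deployment at it.
        """
        ref = ref if isinstance(ref, EntityRef) else EntityRef.parse(ref)
        if not ref.qualifiers:
            return self.url, f"{self.url}/{ref.uid}"
        seen = set()
        for q in ref.qualifiers:
            if q in seen:
                raise CycleError(f"cyclic deployment qualification in {ref}: {q} repeats")
            seen.add(q)
        now = now or self.clock.now()
        registry_url = self.root_url or self.url
        at = registry_url
        for dep_uid in ref.qualifiers:
            if dep_uid == (self.ref.uid if self.ref else None):
                at = self.url
                continue
            at = self._lookup(dep_uid, at, now)
        return at, f"{at}/{ref.uid}"

    # ------------------------------------------------------------------
    # tokens
    def issue_token(self, user: EntityRef | str, now: datetime | None = None,
                    ttl: float = 3600.0) -> Credential:
        """Authenticate-and-issue: a temporary surrogate token for a local user."""
        user = user if isinstance(user, EntityRef) else EntityRef.parse(user)
        if not self.store.exists(user.unqualified()):
            raise AuthenticationError(f"user {user.uid} unknown at deployment {self.ref.uid}")
        now = now or self.clock.now()
        token = f"{self.ref.uid}-{self.rng.getrandbits(64):016x}"
        self._tokens[token] = (user.uid, now + timedelta(seconds=ttl))
        qualified = user if user.qualifiers else user.qualified(self.ref.uid)
        return Credential(qualified, token, now, ttl)

    def validate_token(self, credential: Credential,
                       now: datetime | None = None) -> EntityRef:
        """Validate a credential; foreign users delegate to their home
        deployment (the Fig-style select(U.id|U<n>)-with-key handshake)."""
        now = now or self.clock.now()
        user = credential.user
        home_uid = user.qualifiers[-1] if user.qualifiers else self.ref.uid
        if home_uid == self.ref.uid:
            entry = self._tokens.get(credential.token)
            if entry is None:
                raise AuthenticationError("unknown or tampered token")
            uid, expiry = entry
            if now > expiry:
                raise TokenExpiredError(f"token for {uid} expired at {expiry.isoformat()}")
            # the select(U.id|U<n>) check: the token's user must match and exist
            rs = execute(parse_compact(f"select(U.id|{user.uid})", self.store.core), self.store)
            if uid != user.uid or not rs.rows:
                raise AuthenticationError(
                    f"token does not identify {user.uid} (U.id mismatch)")
            return user if user.qualifiers else user.qualified(self.ref.uid)
        # delegate to home deployment, dereferencing its URL via the root
        home_url = self._lookup(home_uid, self.root_url or self.url, now)
        home = self.network.by_url(home_url)
        return home.validate_token(credential, now)

    # ------------------------------------------------------------------
    # federated execution
    def federated_select(self, q: S3QLQuery | str, credential: Credential,
                         now: datetime | None = None) -> ResultSet:
        """Run a select whose filter carries a deployment qualifier.

        Resolves the holding deployment, validates the requesting user
        against their home deployment, strips the qualifier and executes
        locally there under the holder's permission gating.  Failed
        validation returns no data (raises).
        """
        if isinstance(q, str):
            q = parse_compact(q, self.store.core)
        qualified = [(k, v) for k, v in q.params
                     if isinstance(v, EntityRef) and v.qualifiers]
        if not qualified:
            raise ValidationError("federated select needs a deployment-qualified UID filter")
        key, ref = qualified[0]
        now = now or self.clock.now()
        target_url, _ = self.resolve(ref, now)
        if self.network is None:
            raise ResolutionError("no network transport configured")
        target = self.network.by_url(target_url) if target_url != self.url else self
        user = target.validate_token(credential, now)  # raises on mismatch/expiry
        local_q = q.replace_param(key, ref.unqualified())
        return execute(local_q, target.store, user=str(user))
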