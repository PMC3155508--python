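"""The permission-operator algebra and its propagation.

Rights are encoded as a three-position operator string over the alphabet
``{Y, S, N, y, s, n, -}``; the positions govern, in order, the rights to
*view*, *change* and *use* an entity:

* ``Y`` — full permission; ``S`` — permission limited to the creator of
  the resource; ``N`` — no permission.
* Uppercase symbols are *dominant*, lowercase *recessive*: when several
  states converge on one entity, a dominant symbol overrides a recessive
  one; between two symbols of the same case the more restrictive wins
  (``N`` > ``S`` > ``Y``).  ``-`` marks a missing assignment and is the
  identity of the merge.

The per-position merge is therefore the join of the total order
``- < y < s < n < Y < S < N`` — a commutative, associative, idempotent
monoid with identity ``-``.

States assigned directly to a (user, entity) pair are *assigned*
permissions; *effective* permissions result from propagating assigned
states over the transition matrix derived from the core model's
relationships (parent-to-child), merging wherever states converge.  The
four management actions gate on one position each: ``select`` on view,
``update``/``delete`` on change, ``insert`` on use (checked on every
parent the new instance links to).  A position left ``-`` after
propagation denies — unauthorized users see nothing by default.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .core_model import CoreModel, EntityRef
from .errors import PermissionFormatError

SYMBOLS = "YSNysn-"
POSITIONS = ("view", "change", "use")
ACTION_POSITION = {"select": "view", "update": "change", "delete": "change", "insert": "use"}

#: Namespace under which operator states are minted as RDF predicates.
OPERATOR_NS = "http://s3db.org/operator#"

# Join strength: dominance (case) first, then restrictiveness N > S > Y.
_STRENGTH = {"-": 0, "y": 1, "s": 2, "n": 3, "Y": 4, "S": 5, "N": 6}


def merge_symbol(a: str, b: str) -> str:
    """Join of two position symbols under the declared dominance order."""
    if a == "-":
        return b
    if b == "-":
        return a
    if a.isupper() != b.isupper():
        return a if a.isupper() else b
    order = {"N": 3, "S": 2, "Y": 1}
    return a if order[a.upper()] >= order[b.upper()] else b


@dataclass(frozen=True)
class PermissionState:
    """Three ordered operator positions: view, change, use."""

    view: str = "-"
    change: str = "-"
    use: str = "-"

    def __post_init__(self):
        for pos, sym in zip(POSITIONS, (self.view, self.change, self.use)):
            if sym not in SYMBOLS:
                raise PermissionFormatError(
                    f"invalid symbol {sym!r} at position {pos!r}: alphabet is {SYMBOLS}"
                )

    def __str__(self) -> str:
        return self.view + self.change + self.use

    def symbol(self, position: str) -> str:
        return getattr(self, position)

    def merge(self, other: "PermissionState") -> "PermissionState":
        return PermissionState(
            merge_symbol(self.view, other.view),
            merge_symbol(self.change, other.change),
            merge_symbol(self.use, other.use),
        )

    @classmethod
    def parse(cls, text: str) -> "PermissionState":
        if not isinstance(text, str) or len(text) != 3:
            raise PermissionFormatError(
                f"permission state must be exactly 3 characters over {SYMBOLS}, got {text!r}"
            )
        return cls(*text)


UNASSIGNED = PermissionState()


def parse_state(text: str) -> PermissionState:
    """Parse a three-character operator string such as ``"YSN"`` or ``"ysn"``."""
    return PermissionState.parse(text)


def merge(a: PermissionState, b: PermissionState) -> PermissionState:
    """Merge two operator states position-wise (see module docstring)."""
    return a.merge(b)


@dataclass(frozen=True)
class PermissionAssignment:
    """The triple [user state target]: an operator state as predicate."""

    user: EntityRef
    target: EntityRef
    state: PermissionState


class TransitionMatrix:
    """Directed graph over entity *instances* along which states propagate.

    Edges are instantiated from the core model's relationships on a
    store's content (parent -> child).  ``memory_length`` bounds the
    number of hops a state travels (``None`` = unlimited).
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = (),
                 memory_length: int | None = None):
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(nodes)
        self.graph.add_edges_from(edges)
        self.memory_length = memory_length

    @property
    def nodes(self):
        return self.graph.nodes

    @classmethod
    def from_store(cls, store, memory_length: int | None = None) -> "TransitionMatrix":
        return cls(store.instance_edges(), store.instance_nodes(), memory_length)


def _as_assigned_map(assignments, user: EntityRef | str | None) -> dict[str, PermissionState]:
    if isinstance(assignments, Mapping):
        return {str(k): v for k, v in assignments.items()}
    user_key = str(user) if user is not None else None
    out: dict[str, PermissionState] = {}
    for a in assignments:
        if user_key is None or str(a.user) == user_key:
            # one assigned state per (user, target): last write wins
            out[str(a.target)] = a.state
    return out


def propagate(assignments, matrix: TransitionMatrix, user: EntityRef | str | None = None,
              memory_length: int | None = None, kernel: str = "merge") -> dict[str, PermissionState]:
    """Effective permission of ``user`` at every node of the matrix.

    ``assignments`` is either a mapping node-uid -> state or an iterable
    of :class:`PermissionAssignment` (filtered by ``user``).  The default
    ``merge`` kernel copies each assigned state along every edge and
    merges at each node (the state also applies where assigned); the
    alternate ``migrate`` kernel moves states to strict descendants only.

    With unlimited memory the result is the least fixpoint of
    ``eff(n) = assigned(n) ⊕ ⨁_{p→n} eff(p)`` — equivalently the merge of
    the assigned states of all ancestors of ``n`` (and ``n`` itself).
    """
    if memory_length is None:
        memory_length = matrix.memory_length
    assigned = _as_assigned_map(assignments, user)
    g = matrix.graph
    for node in list(assigned):
        if node not in g:
            warnings.warn(f"permission assigned to {node!r}, absent from the store; ignored",
                          stacklevel=2)
            del assigned[node]
    eff: dict[str, PermissionState] = {n: UNASSIGNED for n in g.nodes}

    if kernel not in ("merge", "migrate"):
        raise ValueError(f"unknown propagation kernel {kernel!r}")

    if memory_length is None and kernel == "merge":
        # worklist fixpoint over the finite join-semilattice
        for n, st in assigned.items():
            eff[n] = st
        queue = deque(assigned)
        in_queue = set(queue)
        while queue:
            n = queue.popleft()
            in_queue.discard(n)
            for child in g.successors(n):
                new = eff[child].merge(eff[n])
                if new != eff[child]:
                    eff[child] = new
                    if child not in in_queue:
                        queue.append(child)
                        in_queue.add(child)
        return eff

    # bounded memory / migrate kernel: breadth-first contribution from each
    # assigned node to nodes within memory_length hops
    for origin, st in assigned.items():
        dist = {origin: 0}
        q = deque([origin])
        while q:
            n = q.popleft()
            if memory_length is not None and dist[n] >= memory_length:
                continue
            for child in g.successors(n):
                if child not in dist:
                    dist[child] = dist[n] + 1
                    q.append(child)
        for n, d in dist.items():
            if kernel == "migrate" and d == 0:
                continue
            eff[n] = eff[n].merge(st)
    return eff


@dataclass(frozen=True)
class Decision:
    allowed: bool
    position: str
    reason: str

    def __bool__(self) -> bool:
        return self.allowed


def authorize(action: str, effective: PermissionState, is_creator: bool = False) -> Decision:
    """Gate one action on the governing position of an effective state.

    ``Y``/``y`` allow; ``S``/``s`` allow only the creator of the target;
    ``N``/``n`` and ``-`` (nothing derivable) deny.
    """
    position = ACTION_POSITION.get(action)
    if position is None:
        raise ValueError(f"unknown action {action!r}; expected one of {sorted(ACTION_POSITION)}")
    sym = effective.symbol(position)
    if sym in "Yy":
        return Decision(True, position, f"{position}={sym}")
    if sym in "Ss":
        if is_creator:
            return Decision(True, position, f"{position}={sym} and user is creator")
        return Decision(False, position, f"{position}={sym} but user is not the creator")
    if sym in "Nn":
        return Decision(False, position, f"{position}={sym}")
    return Decision(False, position, f"{position} unassigned ('-'): deny by default")
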