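"""Operator algebra laws, propagation fixpoint vs path-enumeration oracle,
action gating and assignment semantics."""

import itertools
import random

import networkx as nx
import pytest

from s3ql import (
    PermissionState,
    TransitionMatrix,
    authorize,
    generate_fixture,
    merge,
    parse_state,
    propagate,
)
from s3ql.errors import PermissionFormatError
from s3ql.permissions import SYMBOLS, UNASSIGNED, merge_symbol

# Independent oracle: the per-position merge is the join (max) of the
# total order  -  <  y < s < n  <  Y < S < N  (dominance before
# restrictiveness), frozen here as an explicit ranking.
ORACLE_ORDER = "-ysnYSN"


def oracle_merge(a: str, b: str) -> str:
    return max(a, b, key=ORACLE_ORDER.index)


class TestParseState:
    def test_positional_mapping(self):
        st = parse_state("YSN")
        assert (st.view, st.change, st.use) == ("Y", "S", "N")
        assert str(st) == "YSN"

    def test_dashes_mean_unassigned(self):
        assert parse_state("---") == UNASSIGNED

    @pytest.mark.parametrize("bad", ["YSX", "YS", "YSNN", "", "y s"])
    def test_format_errors(self, bad):
        with pytest.raises(PermissionFormatError):
            parse_state(bad)


class TestMergeAlgebra:
    def test_fig_merge_ysn_with_Ndashdash_is_Nsn(self):
        assert str(merge(parse_state("ysn"), parse_state("N--"))) == "Nsn"

    def test_dash_state_is_identity(self):
        for text in ("ysn", "YSN", "N--", "---", "yNs"):
            st = parse_state(text)
            assert merge(st, UNASSIGNED) == st
            assert merge(UNASSIGNED, st) == st

    def test_per_position_merge_equals_oracle_exhaustively(self):
        """Full 7x7 table against the declared-order join oracle."""
        for a, b in itertools.product(SYMBOLS, repeat=2):
            assert merge_symbol(a, b) == oracle_merge(a, b), (a, b)

    def test_commutativity_full_49_pairs(self):
        for a, b in itertools.product(SYMBOLS, repeat=2):
            assert merge_symbol(a, b) == merge_symbol(b, a)

    def test_associativity_all_343_triples(self):
        for a, b, c in itertools.product(SYMBOLS, repeat=3):
            assert merge_symbol(merge_symbol(a, b), c) == merge_symbol(a, merge_symbol(b, c))

    def test_idempotence(self):
        for a in SYMBOLS:
            assert merge_symbol(a, a) == a

    def test_dominant_always_beats_recessive(self):
        for upper in "YSN":
            for lower in "ysn":
                assert merge_symbol(upper, lower) == upper


def path_enumeration_oracle(assigned, graph):
    """Effective state = merge of assigned states over all ancestors
    (including the node itself) — valid on DAGs with unlimited memory."""
    out = {}
    for node in graph.nodes:
        state = assigned.get(node, UNASSIGNED)
        for anc in nx.ancestors(graph, node):
            if anc in assigned:
                state = state.merge(assigned[anc])
        out[node] = state
    return out


class TestPropagation:
    def test_gi_scenario_effective_states(self, gi):
        """Project 'ysn' is inherited by sibling collections and rules;
        an assigned 'N--' on Demographics forces 'Nsn' on it and on all
        related rules and items."""
        store = gi.store
        eff = store.effective_permissions(gi.refs["gi_user1"])
        assert str(eff[gi.refs["demographics"].uid]) == "Nsn"
        assert str(eff[gi.refs["tissue"].uid]) == "ysn"
        assert str(eff[gi.refs["outcomes"].uid]) == "ysn"
        assert str(eff[gi.refs["rule_name"].uid]) == "Nsn"
        assert str(eff[gi.refs["rule_age"].uid]) == "Nsn"
        assert str(eff[gi.refs["patient1"].uid]) == "Nsn"
        assert str(eff[gi.refs["rule_tissue"].uid]) == "ysn"

    def test_no_assignments_is_deny_by_default_everywhere(self, gi):
        store = gi.store
        eff = store.effective_permissions("U999")
        assert all(state == UNASSIGNED for state in eff.values())
        for action in ("select", "insert", "update", "delete"):
            assert not authorize(action, UNASSIGNED)

    def test_removing_the_restrictive_assignment_restores_ysn(self, gi):
        store = gi.store
        store.remove_permission(gi.refs["gi_user1"], gi.refs["demographics"])
        eff = store.effective_permissions(gi.refs["gi_user1"])
        assert str(eff[gi.refs["demographics"].uid]) == "ysn"

    def test_adding_an_assignment_never_relaxes_below_merge(self, gi):
        """Monotonicity: each effective position is at least as strong as
        merge of before-state and the propagated contribution."""
        store = gi.store
        user = gi.refs["gi_user2"]
        before = store.effective_permissions(user)
        store.assign_permission(user, gi.refs["outcomes"], "N--")
        after = store.effective_permissions(user)
        for uid, b in before.items():
            for pos in ("view", "change", "use"):
                a_sym, b_sym = after[uid].symbol(pos), b.symbol(pos)
                # each position only climbs the join order, never descends
                assert ORACLE_ORDER.index(a_sym) >= ORACLE_ORDER.index(b_sym)

    @pytest.mark.parametrize("seed", range(50))
    def test_fixpoint_equals_path_enumeration_on_random_stores(self, seed):
        fx = generate_fixture("random", seed=seed, n_nodes=random.Random(seed).randint(8, 30))
        store = fx.store
        matrix = store.transition_matrix()
        assert nx.is_directed_acyclic_graph(matrix.graph)
        rng = random.Random(1000 + seed)
        nodes = sorted(matrix.graph.nodes)
        assigned = {}
        for node in rng.sample(nodes, k=min(len(nodes), rng.randint(1, 6))):
            assigned[node] = PermissionState(*(rng.choice(SYMBOLS) for _ in range(3)))
        assert propagate(assigned, matrix) == path_enumeration_oracle(assigned, matrix.graph)

    def test_memory_length_bounds_propagation_depth(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        matrix = TransitionMatrix(edges)
        assigned = {"a": parse_state("N--")}
        eff1 = propagate(assigned, matrix, memory_length=1)
        assert str(eff1["b"]) == "N--" and eff1["c"] == UNASSIGNED
        eff_all = propagate(assigned, matrix)
        assert str(eff_all["d"]) == "N--"

    def test_migrate_kernel_moves_state_off_its_origin(self):
        matrix = TransitionMatrix([("a", "b")])
        eff = propagate({"a": parse_state("Y--")}, matrix, kernel="migrate")
        assert eff["a"] == UNASSIGNED and str(eff["b"]) == "Y--"

    def test_assignment_to_absent_node_warns_and_is_ignored(self):
        matrix = TransitionMatrix([("a", "b")])
        with pytest.warns(UserWarning, match="absent"):
            eff = propagate({"ghost": parse_state("Y--")}, matrix)
        assert eff["a"] == UNASSIGNED

    def test_dominant_state_propagates_as_dominant(self):
        matrix = TransitionMatrix([("a", "b")])
        eff = propagate({"a": parse_state("N--"), "b": parse_state("y--")}, matrix)
        assert str(eff["b"]) == "N--"


class TestAuthorize:
    def test_positions_govern_their_actions(self):
        st = parse_state("YNn")
        assert authorize("select", st)
        assert not authorize("update", st)
        assert not authorize("delete", st)
        assert not authorize("insert", st)

    def test_s_allows_only_the_creator(self):
        st = parse_state("-s-")
        assert authorize("update", st, is_creator=True)
        assert not authorize("update", st, is_creator=False)

    def test_yyy_allows_all_four(self):
        st = parse_state("YYY")
        for action in ("select", "insert", "update", "delete"):
            assert authorize(action, st)

    def test_denial_carries_governing_position(self):
        dec = authorize("insert", parse_state("yy-"))
        assert not dec.allowed and dec.position == "use"


class TestAssignment:
    def test_reassignment_overwrites(self, gi):
        store = gi.store
        user, target = gi.refs["gi_user2"], gi.refs["outcomes"]
        store.assign_permission(user, target, "Y--")
        store.assign_permission(user, target, "n--")
        assert str(store.assignments_for(user)[target.uid]) == "n--"

    def test_use_grant_permits_item_insertion_fig6(self, gi):
        """gi_user2 (use on TissueData) may insert Items there; gi_user1 may not."""
        from s3ql import execute, parse_compact
        from s3ql.errors import PermissionDenied
        store = gi.store
        q = parse_compact(f"insert(I|{gi.refs['tissue'].uid},label=new-sample)", store.core)
        with pytest.raises(PermissionDenied) as exc:
            execute(q, store, user=gi.refs["gi_user1"])
        assert exc.value.position == "use"
        result = execute(q, store, user=gi.refs["gi_user2"])
        assert result.ref is not None

    def test_use_n_on_rule_blocks_statements_via_it(self, gi):
        """Effective use='n' on a Rule prevents creating Statements using it."""
        from s3ql import execute, parse_compact
        from s3ql.errors import PermissionDenied
        store = gi.store
        item = gi.refs["sample1"]
        rule = gi.refs["rule_tissue"]
        q = parse_compact(f"insert(S|{item.uid},{rule.uid},value=x)", store.core)
        # gi_user1 has effective use 'n' on the rule (inherited from ysn)
        with pytest.raises(PermissionDenied):
            execute(q, store, user=gi.refs["gi_user1"])
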