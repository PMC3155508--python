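"""Typed named-graph store: contextual descriptors, rule-as-predicate,
soft deletion and lossless quad round trips."""

import pytest
from rdflib import Dataset, URIRef

from s3ql import EntityRef, Store
from s3ql.clock import SimClock
from s3ql.errors import (
    DependencyError,
    DomainViolationError,
    ImmutableAttributeError,
    NotFoundError,
    TypeMismatchError,
    ValidationError,
)


@pytest.fixture()
def store():
    return Store(clock=SimClock())


@pytest.fixture()
def populated(store):
    user = store.insert_entity("User", {"label": "alice"})
    project = store.insert_entity("Project", {"label": "Test"}, user)
    people = store.insert_entity("Collection", {"label": "Person", "project_id": project}, user)
    ages = store.insert_entity("Collection", {"label": "Age", "project_id": project}, user)
    rule = store.add_rule(people, "hasAge", "Age", user, number=12)
    john = store.insert_entity("Item", {"label": "John", "collection_id": people}, user)
    stmt = store.add_statement(john, rule, "26", user)
    return dict(store=store, user=user, project=project, people=people, ages=ages,
                rule=rule, john=john, stmt=stmt)


class TestInsert:
    def test_insert_stamps_system_descriptors(self, store):
        user = store.insert_entity("User", {"label": "alice"})
        ref = store.insert_entity("Project", {"label": "Test"}, acting_user=user)
        rec = store.get(ref)
        assert rec.creator == user
        assert rec.created.endswith("Z")
        assert rec.label == "Test"

    def test_consecutive_inserts_mint_distinct_sequential_uids(self, store):
        a = store.insert_entity("Project", {"label": "a"})
        b = store.insert_entity("Project", {"label": "b"})
        assert a != b
        assert b.number == a.number + 1

    def test_collection_without_project_cites_pc(self, store):
        with pytest.raises(DependencyError) as exc:
            store.insert_entity("Collection", {"label": "orphan"})
        assert exc.value.relationship == "PC"
        assert "project_id" in str(exc.value)

    def test_unknown_attribute_rejected(self, store):
        with pytest.raises(ValidationError, match="prefLabel"):
            store.insert_entity("Project", {"prefLabel": "x"})

    def test_system_attribute_in_params_rejected(self, store):
        with pytest.raises(ImmutableAttributeError):
            store.insert_entity("Project", {"creator": "U9"})


class TestRulesAndStatements:
    def test_rule_graph_holds_the_domain_triple(self, populated):
        store, rule = populated["store"], populated["rule"]
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        graph = ds.graph(store.uri(rule))
        triples = list(graph)
        assert len(triples) == 1
        s, p, o = triples[0]
        assert s == store.uri(populated["people"])
        assert "hasAge" in str(p)

    def test_statement_predicate_is_the_rule_graph_name(self, populated):
        store = populated["store"]
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        graph = ds.graph(store.uri(populated["stmt"]))
        ((s, p, o),) = list(graph)
        assert s == store.uri(populated["john"])
        assert p == store.uri(populated["rule"])
        assert str(o) == "26"

    def test_rule_subject_must_be_collection(self, populated):
        store = populated["store"]
        with pytest.raises(TypeMismatchError):
            store.add_rule(populated["john"], "hasX", "X")

    def test_renaming_verb_leaves_statements_intact(self, populated):
        store = populated["store"]
        before = store.get(populated["stmt"]).attrs.copy()
        store.update_entity(populated["rule"], {"verb": "hasAgeInYears"})
        assert store.get(populated["stmt"]).attrs == before
        # the statement still resolves through the rule ref
        assert store.get(populated["rule"]).attrs["verb"] == "hasAgeInYears"

    def test_statement_from_wrong_collection_is_domain_violation(self, populated):
        store = populated["store"]
        other = store.insert_entity("Item", {"label": "age-item",
                                             "collection_id": populated["ages"]})
        with pytest.raises(DomainViolationError):
            store.add_statement(other, populated["rule"], "7")

    def test_item_valued_statement_accepted_and_object_typed(self, populated):
        store = populated["store"]
        rule2 = store.add_rule(populated["people"], "hasAgeClass", populated["ages"])
        age_item = store.insert_entity("Item", {"label": "adult",
                                                "collection_id": populated["ages"]})
        stmt = store.add_statement(populated["john"], rule2, age_item)
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        ((s, p, o),) = list(ds.graph(store.uri(stmt)))
        assert o == store.uri(age_item)  # object is the item's URI, not a literal


class TestUpdateDelete:
    def test_update_rewrites_label_but_not_creator(self, populated):
        store = populated["store"]
        store.update_entity(populated["project"], {"label": "Test2"}, comment="rename")
        rec = store.get(populated["project"])
        assert rec.label == "Test2"
        assert rec.creator == populated["user"]
        assert rec.changes[-1][2] == "rename"

    def test_update_of_system_attribute_is_immutability_error(self, populated):
        with pytest.raises(ImmutableAttributeError):
            populated["store"].update_entity(populated["project"], {"created": "now"})

    def test_update_unknown_ref_not_found(self, store):
        with pytest.raises(NotFoundError):
            store.update_entity(EntityRef.parse("P999"), {"label": "x"})

    def test_delete_is_soft_and_hides_from_selects(self, populated):
        store = populated["store"]
        store.delete_entity(populated["stmt"])
        assert store.select("Statement") == []
        with pytest.raises(NotFoundError):
            store.get(populated["stmt"])
        # still present when deprecation is included
        assert store.get(populated["stmt"], include_deprecated=True).deprecated

    def test_deleted_graph_exported_with_flag(self, populated):
        store = populated["store"]
        store.delete_entity(populated["stmt"])
        without = store.export_quads("nquads")
        assert str(store.uri(populated["stmt"])) not in without
        with_dep = store.export_quads("nquads", include_deprecated=True)
        assert str(store.uri(populated["stmt"])) in with_dep
        assert "deprecated" in with_dep


class TestExportImport:
    def test_contextual_completeness(self, populated):
        """Every non-deprecated graph has exactly one id, created, creator."""
        store = populated["store"]
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        from rdflib.namespace import DCTERMS
        from rdflib import Namespace, RDF
        ns = Namespace(store.core.namespace)
        subjects = set(ds.subjects(RDF.type, None))
        assert len(subjects) == len(store.records)
        for s in subjects:
            assert len(list(ds.objects(s, ns.id))) == 1
            assert len(list(ds.objects(s, DCTERMS.created))) == 1
            assert len(list(ds.objects(s, DCTERMS.creator))) == 1

    def test_rule_plus_statement_yields_two_content_graphs(self, populated):
        store = populated["store"]
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        named = [g for g in ds.graphs() if len(g) and str(g.identifier) != "urn:x-rdflib:default"]
        assert {str(g.identifier).rsplit("/", 1)[-1] for g in named} == {"R12", "S1"}

    @pytest.mark.parametrize("fmt", ["trig", "nquads"])
    def test_round_trip_is_isomorphic(self, populated, fmt):
        store = populated["store"]
        text = store.export_quads(fmt, include_deprecated=True)
        again = Store.import_quads(text, fmt)
        assert again.canonical_export() == store.canonical_export()

    def test_empty_store_serializes_to_deployment_only(self):
        store = Store(clock=SimClock())
        ds = Dataset()
        ds.parse(data=store.export_quads("trig"), format="trig")
        from rdflib import RDF
        assert len(list(ds.subjects(RDF.type, None))) == 1  # just the deployment graph

    def test_malformed_input_raises_parse_error(self):
        from s3ql.errors import ParseError
        with pytest.raises(ParseError):
            Store.import_quads("this is } not trig {", "trig")

    def test_turtle_export_is_lossy_but_parseable(self, populated):
        from rdflib import Graph
        text = populated["store"].export_quads("turtle")
        g = Graph()
        g.parse(data=text, format="turtle")
        assert len(g) > 0
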