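"""Deterministic demo scenarios for tests, examples and the CLI.

Three scenarios are provided:

``gi_trials``
    A single deployment emulating a gastrointestinal clinical-trials
    project: Collections *Demographics*, *TissueData* and *Outcomes*
    with Rules, Items and Statements, and two users — ``gi_user1``
    holds ``ysn`` on the project plus a restrictive ``N--`` on
    Demographics; ``gi_user2`` holds ``ysn`` on the project plus a
    permissive ``--Y`` (use) on TissueData.  Content values are
    illustrative, invented to instantiate the structure.
``mlst_mini``
    Three deployments behind one root registry for the federated
    walkthrough: a home deployment holding user U78 and a data
    deployment holding multilocus-sequence-typing style profile
    statements under rule R172930.
``random``
    A randomly populated single deployment (projects, collections,
    rules, items, statements) used by the propagation-oracle property
    tests.

Identical ``(scenario, seed)`` always yields identical store content —
byte-identical canonical exports — by combining a stepped simulation
clock with a seeded random generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .clock import SimClock
from .core_model import EntityRef
from .errors import S3QLError
from .federation import Deployment, Network

SCENARIOS = ("gi_trials", "mlst_mini", "random")


@dataclass
class FixtureSpec:
    scenario: str = "gi_trials"
    seed: int = 0
    n_nodes: int = 20  # target size for the random scenario


@dataclass
class Fixture:
    """A populated network plus named handles into its content."""

    network: Network
    deployments: dict[str, Deployment]
    refs: dict[str, EntityRef] = field(default_factory=dict)

    @property
    def deployment(self) -> Deployment:
        return next(iter(self.deployments.values()))

    @property
    def store(self):
        return self.deployment.store


def generate_fixture(spec: FixtureSpec | str = "gi_trials", seed: int | None = None,
                     **kwargs) -> Fixture:
    if isinstance(spec, str):
        spec = FixtureSpec(scenario=spec, seed=seed if seed is not None else 0, **kwargs)
    elif seed is not None:
        spec.seed = seed
    if spec.scenario == "gi_trials":
        return _gi_trials(spec)
    if spec.scenario == "mlst_mini":
        return _mlst_mini(spec)
    if spec.scenario == "random":
        return _random_store(spec)
    raise S3QLError(f"unknown scenario {spec.scenario!r}; available: {', '.join(SCENARIOS)}")


def _gi_trials(spec: FixtureSpec) -> Fixture:
    rng = random.Random(spec.seed)
    clock = SimClock()
    net = Network()
    dep = Deployment(1, "http://gi.example.org/s3db", network=net, clock=clock,
                     rng=random.Random(spec.seed + 1), label="GI trials deployment")
    s = dep.store
    admin = s.insert_entity("User", {"label": "admin", "mbox": "admin@gi.example.org"})
    # make the admin the deployment's creator so execute() treats it as such
    s.records[s.deployment.uid].creator = admin
    u1 = s.insert_entity("User", {"label": "gi_user1", "mbox": "gi_user1@gi.example.org"}, admin)
    u2 = s.insert_entity("User", {"label": "gi_user2", "mbox": "gi_user2@gi.example.org"}, admin)
    project = s.insert_entity("Project", {"label": "GI Clinical Trials",
                                          "description": "gastrointestinal clinical trials"},
                              admin)
    demographics = s.insert_entity("Collection", {"label": "Demographics", "project_id": project}, admin)
    tissue = s.insert_entity("Collection", {"label": "TissueData", "project_id": project}, admin)
    outcomes = s.insert_entity("Collection", {"label": "Outcomes", "project_id": project}, admin)
    r_name = s.add_rule(demographics, "hasPatientName", "Name", admin)
    r_age = s.add_rule(demographics, "hasAge", "Age", admin)
    r_type = s.add_rule(tissue, "hasTissueType", "TissueType", admin)
    r_resp = s.add_rule(outcomes, "hasResponse", "Response", admin)
    items = {}
    for i in range(1, 3):
        patient = s.insert_entity("Item", {"label": f"patient-{i}", "collection_id": demographics}, admin)
        items[f"patient{i}"] = patient
        s.add_statement(patient, r_name, f"Patient {i}", admin)
        s.add_statement(patient, r_age, str(rng.randint(35, 80)), admin)
    sample = s.insert_entity("Item", {"label": "sample-1", "collection_id": tissue}, admin)
    items["sample1"] = sample
    s.add_statement(sample, r_type, rng.choice(["adenocarcinoma", "normal mucosa"]), admin)
    outcome = s.insert_entity("Item", {"label": "outcome-1", "collection_id": outcomes}, admin)
    items["outcome1"] = outcome
    s.add_statement(outcome, r_resp, rng.choice(["partial response", "stable disease"]), admin)
    # Fig-style permission assignments
    s.assign_permission(u1, project, "ysn")
    s.assign_permission(u1, demographics, "N--")
    s.assign_permission(u2, project, "ysn")
    s.assign_permission(u2, tissue, "--Y")
    refs = {"admin": admin, "gi_user1": u1, "gi_user2": u2, "project": project,
            "demographics": demographics, "tissue": tissue, "outcomes": outcomes,
            "rule_name": r_name, "rule_age": r_age, "rule_tissue": r_type,
            "rule_response": r_resp, **items}
    return Fixture(net, {"D1": dep}, refs)


def _mlst_mini(spec: FixtureSpec) -> Fixture:
    rng = random.Random(spec.seed)
    clock = SimClock()
    net = Network()
    root = Deployment(1016666, "http://root.example.org/s3db", network=net, clock=clock,
                      rng=random.Random(spec.seed + 1), label="root registry")
    home = Deployment(309, "http://home.example.org/s3db", network=net,
                      root_url=root.url, clock=clock, rng=random.Random(spec.seed + 2),
                      label="home deployment")
    data = Deployment(327, "http://data.example.org/s3db", network=net,
                      root_url=root.url, clock=clock, rng=random.Random(spec.seed + 3),
                      label="typing-data deployment")
    root.register_deployment("D309", home.url, title="home deployment")
    root.register_deployment("D327", data.url, title="typing-data deployment")
    user = home.store.insert_entity("User", {"label": "mlst_user",
                                             "mbox": "mlst_user@home.example.org"}, number=78)
    s = data.store
    admin = s.insert_entity("User", {"label": "curator"})
    s.records[s.deployment.uid].creator = admin
    project = s.insert_entity("Project", {"label": "Staphylococcus reference database"}, admin)
    strains = s.insert_entity("Collection", {"label": "Strains", "project_id": project}, admin)
    profile_rule = s.add_rule(strains, "hasAlleleProfile", "Profile", admin, number=172930)
    st_rule = s.add_rule(strains, "hasSequenceType", "SequenceType", admin, number=167271)
    strain_items = {}
    for name in ("PT1", "PT2", "PT15", "PT21"):
        item = s.insert_entity("Item", {"label": name, "collection_id": strains}, admin)
        strain_items[name] = item
        profile = "-".join(str(rng.randint(1, 12)) for _ in range(7))
        s.add_statement(item, profile_rule, profile, admin)
        s.add_statement(item, st_rule, str(rng.randint(1, 40)), admin)
    # the foreign user may view the typing data
    qualified_user = f"D309:U{78}"
    s.assign_permission(qualified_user, project, "y--")
    refs = {"user": EntityRef.parse("U78").qualified("D309"), "project": project,
            "strains": strains, "profile_rule": profile_rule, "st_rule": st_rule,
            **strain_items}
    return Fixture(net, {"D1016666": root, "D309": home, "D327": data}, refs)


def _random_store(spec: FixtureSpec) -> Fixture:
    rng = random.Random(spec.seed)
    clock = SimClock()
    net = Network()
    dep = Deployment(1, "http://random.example.org/s3db", network=net, clock=clock,
                     rng=random.Random(spec.seed + 1), label="random deployment")
    s = dep.store
    users = [s.insert_entity("User", {"label": f"user-{i}"}) for i in range(rng.randint(1, 3))]
    budget = max(4, spec.n_nodes - len(users) - 1)
    projects = [s.insert_entity("Project", {"label": f"project-{i}"})
                for i in range(rng.randint(1, 2))]
    budget -= len(projects)
    collections, rules, item_list = [], [], []
    while budget > 0:
        kind = rng.random()
        if kind < 0.3 or not collections:
            collections.append(s.insert_entity(
                "Collection", {"label": f"c{budget}", "project_id": rng.choice(projects)}))
        elif kind < 0.55:
            rules.append(s.add_rule(rng.choice(collections), f"verb{budget}", "Value"))
        elif kind < 0.8:
            item_list.append(s.insert_entity(
                "Item", {"label": f"i{budget}", "collection_id": rng.choice(collections)}))
        elif rules and item_list:
            rule = rng.choice(rules)
            domain = s.get(rule).attrs["subject_id"]
            members = [i for i in item_list
                       if str(s.get(i).attrs["collection_id"]) == str(domain)]
            if members:
                s.add_statement(rng.choice(members), rule, str(rng.randint(0, 99)))
        budget -= 1
    refs = {"user": users[0], "project": projects[0]}
    return Fixture(net, {"D1": dep}, refs)
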