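{
  "name": "s3db",
  "namespace": "http://s3db.org/core#",
  "entities": [
    {
      "name": "Deployment",
      "letter": "D",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "url": "submitter",
        "deployment_id": "submitter"
      }
    },
    {
      "name": "User",
      "letter": "U",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "mbox": "submitter"
      }
    },
    {
      "name": "Project",
      "letter": "P",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "project_id": "submitter"
      }
    },
    {
      "name": "Collection",
      "letter": "C",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "project_id": "submitter"
      }
    },
    {
      "name": "Rule",
      "letter": "R",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "subject_id": "submitter",
        "verb": "submitter",
        "object": "submitter"
      }
    },
    {
      "name": "Item",
      "letter": "I",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "collection_id": "submitter"
      }
    },
    {
      "name": "Statement",
      "letter": "S",
      "attributes": {
        "id": "system",
        "label": "submitter",
        "description": "submitter",
        "creator": "system",
        "created": "system",
        "item_id": "submitter",
        "rule_id": "submitter",
        "value": "submitter"
      }
    }
  ],
  "relationships": [
    {"name": "DD", "from": "Deployment", "to": "Deployment", "attribute": "deployment_id", "required": false,
     "meaning": "a deployment registered under a root deployment"},
    {"name": "DU", "from": "Deployment", "to": "User", "attribute": null, "required": false,
     "meaning": "a user account belongs to a deployment"},
    {"name": "DP", "from": "Deployment", "to": "Project", "attribute": null, "required": false,
     "meaning": "a project is hosted by a deployment"},
    {"name": "PP", "from": "Project", "to": "Project", "attribute": "project_id", "required": false,
     "meaning": "a subproject depends on its parent project"},
    {"name": "PC", "from": "Project", "to": "Collection", "attribute": "project_id", "required": true,
     "meaning": "a collection depends on the project it belongs to"},
    {"name": "PR", "from": "Project", "to": "Rule", "attribute": null, "required": false,
     "meaning": "a rule belongs to the project of its subject collection"},
    {"name": "CR", "from": "Collection", "to": "Rule", "attribute": "subject_id", "required": true,
     "meaning": "a rule's subject is a collection (rdfs:domain)"},
    {"name": "OR", "from": "Collection", "to": "Rule", "attribute": "object", "required": false,
     "meaning": "a rule's object may be a collection (rdfs:range)"},
    {"name": "CI", "from": "Collection", "to": "Item", "attribute": "collection_id", "required": true,
     "meaning": "an item instantiates a collection"},
    {"name": "RS", "from": "Rule", "to": "Statement", "attribute": "rule_id", "required": true,
     "meaning": "a statement instantiates a rule (rule-as-predicate)"},
    {"name": "IS", "from": "Item", "to": "Statement", "attribute": "item_id", "required": true,
     "meaning": "a statement describes an item"},
    {"name": "SS", "from": "Statement", "to": "Statement", "attribute": "value", "required": false,
     "meaning": "a statement may reuse another statement as its value"}
  ]
}
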