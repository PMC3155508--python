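{
  "name": "skos",
  "namespace": "http://www.w3.org/2004/02/skos/core#",
  "entities": [
    {
      "name": "Scheme",
      "letter": "S",
      "attributes": {
        "id": "system",
        "creator": "system",
        "created": "system",
        "prefLabel": "submitter",
        "definition": "submitter"
      }
    },
    {
      "name": "Concept",
      "letter": "C",
      "attributes": {
        "id": "system",
        "creator": "system",
        "created": "system",
        "prefLabel": "submitter",
        "altLabel": "submitter",
        "definition": "submitter",
        "notation": "submitter",
        "inScheme": "submitter",
        "broader": "submitter"
      }
    }
  ],
  "relationships": [
    {"name": "SC", "from": "Scheme", "to": "Concept", "attribute": "inScheme", "required": false,
     "meaning": "a concept is in a concept scheme"},
    {"name": "CC", "from": "Concept", "to": "Concept", "attribute": "broader", "required": false,
     "meaning": "a concept has a broader concept"}
  ]
}
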