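"""Translate queries between the compact and XML flavours.

The compact form ``action(E | E.a = value)`` reads the ``|`` as "given
that"; a bare UID such as ``P156`` is shorthand for ``project_id = 156``.
Both flavours carry the same information, so translation is lossless.
"""

from s3ql import default_core, load_core_model, translate

core = default_core()

compact = "insert(P | label = Test)"
xml = translate(compact, core, to="xml")
print(f"compact: {compact}\nXML:\n{xml}\n")
print("back to compact:", translate(xml, core, to="compact"))

# The language is not tied to the default core model: point it at the
# bundled SKOS core and concept queries become valid.
skos = load_core_model("skos")
print("\nunder the skos core:")
print(translate("select(C|prefLabel = animal)", skos, to="xml"))
# The XML names the entity 'concept': the same four-action surface now
# manages SKOS concepts instead of the default model's collections.
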