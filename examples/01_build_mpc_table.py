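"""Build the medicinal-property-concept (MPC) table from the Thai lexicon.

Property terms are scanned with the verb-anchored word-co pattern; symptom
terms are prefixed with every solving verb of the svc subset.  The printed
keys are the exact lookup strings later matched against corpus EDUs.
"""

from herbrel import examples_data as D
from herbrel.lexicon import build_mpc_property, build_mpc_symptom, merge_dedupe

ws = D.thai_word_sets()
table = merge_dedupe(
    build_mpc_property(D.property_lexicon(), ws),
    build_mpc_symptom(D.symptom_lexicon(), ws),
)

print(f"MPC table: {len(table)} keys for {len(table.concepts())} concepts")
for concept in ("Carminative", "Antidiarrhetic", "Aperient_laxative"):
    print(f"  {concept}: {sorted(table.keys_for(concept))}")
print("one symptom-derived key:", "แก้+เจ็บ+คอ", "->", table.entries["แก้+เจ็บ+คอ"])
# Each key is 'solving verb(+...)+symptom words'; a corpus EDU containing the
# same component sequence is read as a mention of the mapped property.
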