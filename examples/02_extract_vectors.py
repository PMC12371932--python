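"""Extract feature vectors from the Thai-basil document excerpt.

The section header names the plant part (Leaf); discourse units with a
solving verb are matched against the MPC table; the result is one symbolic
vector per (herb, part), its binary form, and the plant lookup table.
"""

from herbrel import examples_data as D
from herbrel.corpus_io import parse_document
from herbrel.extraction import run_extraction
from herbrel.lexicon import build_mpc_property, build_mpc_symptom, merge_dedupe

ws = D.thai_word_sets()
mpc = merge_dedupe(
    build_mpc_property(D.property_lexicon(), ws),
    build_mpc_symptom(D.symptom_lexicon(), ws),
)
doc = parse_document(D.BASIL_DOCUMENT_TEXT)
res = run_extraction([doc], mpc, ws)

sv = res.symbolic[0]
print(f"document: {sv.hname}  part: {sv.ppart}")
print("matched properties:", sv.medp_list)
bv = res.binary[0]
print("binary vector: pp bits", bv.pp_indicators.tolist(),
      "| mp bits", bv.mp_indicators.tolist())
print("plant rows:", [(r.hname, r.ppart, r.medp) for r in res.plant_rows])
print("skip report:", res.skip_report)
# Unmatched medicinal EDUs are recall misses: the EDU carries a solving verb
# but its word-co expression is not covered by the lexicon.
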