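"""Word-co pattern derivation, MPC table construction and sense selection."""

import pytest
from hypothesis import given, settings, strategies as st

from herbrel import examples_data as D
from herbrel.lexicon import (
    LexiconEntry,
    SenseCandidate,
    WordSets,
    build_mpc_property,
    build_mpc_symptom,
    derive_word_co,
    merge_dedupe,
    select_sense,
)


@pytest.fixture(scope="module")
def ws():
    return D.thai_word_sets()


class TestDeriveWordCo:
    def test_symptom_word_is_skipped_after_solving_verb(self, ws):
        toks = [("แก้", "V_strong"), ("อาการ", "Noun"),
                ("ปวด", "V_strong"), ("กล้ามเนื้อ", "Noun")]
        assert [e.key for e in derive_word_co(toks, ws)] == ["แก้+ปวด+กล้ามเนื้อ"]

    def test_coordinated_solving_verbs_anchor_separate_expressions(self, ws):
        toks = [("แก้", "V_strong"), ("รักษา", "V_strong"),
                ("อาการ", "Noun"), ("ท้องเสีย", "V_strong")]
        assert {e.key for e in derive_word_co(toks, ws)} == {
            "แก้+ท้องเสีย", "รักษา+ท้องเสีย"
        }

    def test_standalone_expression_yields_bare_key(self, ws):
        assert [e.key for e in derive_word_co([("ผายลม", "V_strong")], ws)] == ["ผายลม"]

    def test_weak_verb_compound_takes_following_strong_verb_slot(self, ws):
        toks = [("เป็น", "V_weak"), ("ยา", "Noun"), ("ระบาย", "V_strong")]
        assert [e.key for e in derive_word_co(toks, ws)] == ["เป็น+ยา+ระบาย"]

    def test_empty_and_svc_free_inputs_give_empty_list(self, ws):
        assert derive_word_co([], ws) == []
        assert derive_word_co([("มี", "V_weak"), ("รส", "Noun")], ws) == []

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_keys_never_contain_stop_or_symptom_words(self, data):
        ws = D.thai_word_sets()
        vocab = ["แก้", "ขับ", "ลม", "ไข้", "ใน", "อาการ", "เป็น", "ยา", "คัน", "ที่"]
        pos = ["V_strong", "V_weak", "Noun", "Adj", "Adv", "Prep"]
        toks = data.draw(
            st.lists(st.tuples(st.sampled_from(vocab), st.sampled_from(pos)), max_size=8)
        )
        for e in derive_word_co(toks, ws):
            comps = set(e.components)
            assert not comps & ws.stop_words
            assert ws.symptom_word not in comps
            assert 1 <= len(e.components) <= 5


class TestMPCConstruction:
    def test_property_fragment_reproduces_expected_keys(self, ws):
        frag = build_mpc_property(D.property_lexicon(), ws)
        by_concept = {}
        for key, concept in frag.entries.items():
            by_concept.setdefault(concept, set()).add(key)
        for concept, keys in D.EXPECTED_PROPERTY_KEYS.items():
            assert by_concept[concept] == keys, concept

    def test_symptom_fragment_size_is_svcsub_times_variants(self, ws):
        frag = build_mpc_symptom(D.symptom_lexicon(), ws)
        n_variants = sum(len(v) for v in D.EXPECTED_SYMPTOM_KEY_TEMPLATES.values())
        assert len(frag.entries) == len(ws.svc_sub) * n_variants
        # spot checks from the expected templates
        assert frag.entries["แก้+เจ็บ+คอ"] == "แก้+sore throat"
        assert frag.entries["ลด+ท้องเฟ้อ"] == "ลด+flatulence"

    def test_symptom_entry_with_only_removable_tokens_is_skip_reported(self, ws):
        entry = LexiconEntry(
            "empty", ((ws.symptom_word, "Noun", "symptom"),), "symptom_term"
        )
        frag = build_mpc_symptom([entry], ws)
        assert not frag.entries
        assert frag.skip_report and frag.skip_report[0]["concept"] == "empty"

    def test_symptom_build_requires_nonempty_svcsub(self, ws):
        bad = WordSets(
            svc=ws.svc, svc_sub=[], stop_words=ws.stop_words,
            symptom_word=ws.symptom_word, wrd_set=ws.wrd_set, pp_set=ws.pp_set,
        )
        with pytest.raises(ValueError):
            build_mpc_symptom(D.symptom_lexicon(), bad)

    def test_merge_collapses_duplicates_and_is_idempotent(self, ws):
        f1 = build_mpc_property(D.property_lexicon(), ws)
        f2 = build_mpc_property(D.property_lexicon(), ws)
        merged = merge_dedupe(f1, f2)
        assert merged.entries == f1.entries
        again = merge_dedupe(f1, f1, f2)
        assert again.entries == merged.entries

    def test_merge_conflict_keeps_first_mapping_and_reports(self, ws):
        a = LexiconEntry("ConceptA", (("ขับ", "V_strong", "expel"), ("ลม", "Noun", "gas")),
                         "property_term")
        b = LexiconEntry("ConceptB", (("ขับ", "V_strong", "expel"), ("ลม", "Noun", "gas")),
                         "property_term")
        merged = merge_dedupe(build_mpc_property([a], ws), build_mpc_property([b], ws))
        assert merged.entries["ขับ+ลม"] == "ConceptA"
        assert merged.conflicts == [
            {"key": "ขับ+ลม", "kept": "ConceptA", "dropped": "ConceptB"}
        ]

    def test_every_key_has_one_to_five_components(self, ws):
        table = merge_dedupe(
            build_mpc_property(D.property_lexicon(), ws),
            build_mpc_symptom(D.symptom_lexicon(), ws),
        )
        assert all(1 <= len(k.split("+")) <= 5 for k in table.entries)


class TestSenseSelection:
    def test_health_domain_sense_wins(self, ws):
        cands = [
            SenseCandidate("transfer", frozenset({"move", "place"})),
            SenseCandidate("excrete", frozenset({"eliminate", "body", "pass"})),
            SenseCandidate("photograph", frozenset({"camera", "picture"})),
        ]
        choice = select_sense(cands, ws)
        assert choice.sense.sense_gloss == "excrete" and choice.confident

    def test_no_intersection_falls_back_with_flag(self, ws):
        cands = [
            SenseCandidate("transfer", frozenset({"move"})),
            SenseCandidate("photograph", frozenset({"camera"})),
        ]
        choice = select_sense(cands, ws)
        assert choice.sense.sense_gloss == "transfer" and not choice.confident

    def test_empty_candidates_raise(self, ws):
        with pytest.raises(ValueError):
            select_sense([], ws)
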