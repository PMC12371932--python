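"""Worked Thai reference examples bundled for tests and documentation.

Contents: the default Thai word sets (solving verbs, plant parts, symptom
word), a small segmented lexicon of medicinal-property and medical-symptom
terms with the word-co keys each is expected to yield, a Thai-basil document
excerpt in the corpus dialect, a published-style table of 27 part -> core
factor path estimates, per-part SVM metric rows, and a small plant table.
All of it is hand-transcribed reference material, kept tiny on purpose.
"""

from __future__ import annotations

from .corpus_io import PlantRow
from .lexicon import LexiconEntry, WordSets
from .sem_paths import PathEstimate

__all__ = [
    "thai_word_sets",
    "property_lexicon",
    "symptom_lexicon",
    "EXPECTED_PROPERTY_KEYS",
    "EXPECTED_SYMPTOM_KEY_TEMPLATES",
    "BASIL_DOCUMENT_TEXT",
    "GASTRO_EDU_TOKENS",
    "reference_path_estimates",
    "PART_INDEX_LABELS",
    "SVM_PART_METRICS",
    "FIG_PLANT_TABLE",
]

# ---------------------------------------------------------------------------
# Word sets
# ---------------------------------------------------------------------------

#: pp_1..pp_9 in canonical order (pp_2 = Rhizome, pp_4 = Leaf).
PART_INDEX_LABELS = {
    1: "WholePlant",
    2: "Rhizome",
    3: "Bark",
    4: "Leaf",
    5: "Flower",
    6: "Fruit",
    7: "Seed",
    8: "Root",
    9: "Shoot",
}

_PP_SET = [
    {"label": "WholePlant", "tokens": ["ทั้งต้น"]},
    {"label": "Rhizome", "tokens": ["ลำต้นใต้ดิน", "เหง้า"]},
    {"label": "Bark", "tokens": ["เปลือกต้น"]},
    {"label": "Leaf", "tokens": ["ใบ", "ใบและก้าน"]},
    {"label": "Flower", "tokens": ["ดอก"]},
    {"label": "Fruit", "tokens": ["ผล"]},
    {"label": "Seed", "tokens": ["เมล็ด"]},
    {"label": "Root", "tokens": ["ราก"]},
    {"label": "Shoot", "tokens": ["หน่อ"]},
]

_SVC = [
    ("แก้",), ("รักษา",), ("ห้าม",), ("เพิ่ม",), ("ลด",), ("บรรเทา",),
    ("ขับ",), ("สมาน",), ("ขจัด",), ("ขับถ่าย",), ("ถ่าย",), ("ระบาย",),
    ("ต้าน",), ("ฆ่า",), ("ผายลม",),
    ("เป็น", "ยา"), ("ช่วย", "ขับ"), ("ใช้", "รักษา"),
]

_SVC_SUB = [("แก้",), ("รักษา",), ("ห้าม",), ("เพิ่ม",), ("ลด",), ("บรรเทา",), ("ขจัด",)]


def thai_word_sets() -> WordSets:
    """The default Thai configuration word sets."""
    return WordSets(
        svc=list(_SVC),
        svc_sub=list(_SVC_SUB),
        stop_words={"ใน", "และ", "หรือ", "ที่"},
        symptom_word="อาการ",
        wrd_set={"patient", "healthy", "illness", "body", "wound"},
        pp_set=[dict(p) for p in _PP_SET],
    )


# ---------------------------------------------------------------------------
# Lexicon (property terms; one LexiconEntry per surface expression)
# ---------------------------------------------------------------------------

def _prop(label: str, *exprs: list[tuple[str, str, str]]) -> list[LexiconEntry]:
    return [
        LexiconEntry(label, tuple(expr), "property_term", entry_id=f"{label}:{k}")
        for k, expr in enumerate(exprs)
    ]


def property_lexicon() -> list[LexiconEntry]:
    N, Vs, Vw, Aj = "Noun", "V_strong", "V_weak", "Adj"
    entries: list[LexiconEntry] = []
    entries += _prop(
        "Antidiarrhetic",
        [("แก้", Vs, "cure"), ("รักษา", Vs, "cure"), ("อาการ", N, "symptom"),
         ("ท้องเสีย", Vs, "have diarrhea")],
    )
    entries += _prop(
        "Antiemetic",
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("อาเจียน", Vs, "vomit")],
    )
    entries += _prop(
        "Antihemorrhagic",
        [("ยา", N, "medicine"), ("ห้าม", Vs, "stop"), ("เลือด", N, "blood")],
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("เลือดออก", Vs, "bleed")],
    )
    entries += _prop(
        "Anti-inflammatory",
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("อักเสบ", Vs, "inflame")],
    )
    entries += _prop(
        "Antipruritic",
        [("ยา", N, "medicine"), ("ลด", Vs, "reduce"), ("อาการ", N, "symptom"),
         ("คัน", Vs, "itch")],
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("คัน", Vs, "itch")],
    )
    entries += _prop(
        "Antipyretic",
        [("ยา", N, "medicine"), ("ลด", Vs, "reduce"), ("ไข้", N, "fever")],
    )
    entries += _prop(
        "Antitussive",
        [("ยา", N, "medicine"), ("บรรเทา", Vs, "relieve"), ("อาการ", N, "symptom"),
         ("ไอ", Vs, "cough")],
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("ไอ", Vs, "cough")],
    )
    entries += _prop(
        "Antiviral",
        [("ยา", N, "medicine"), ("ต้าน", Vs, "resist"), ("เชื้อไวรัส", N, "virus")],
        [("ยา", N, "medicine"), ("ต้าน", Vs, "resist"), ("ไวรัส", N, "virus")],
    )
    entries += _prop(
        "Aperient_laxative",
        [("เป็น", Vw, "be"), ("ยา", N, "medicine"), ("ระบาย", Vs, "release")],
        [("เป็น", Vw, "be"), ("ยา", N, "medicine"), ("ถ่าย", Vs, "excrete")],
        [("ยา", N, "medicine"), ("แก้", Vs, "cure"), ("ท้องผูก", Vs, "be constipated")],
    )
    entries += _prop(
        "Astringent",
        [("เป็น", Vw, "be"), ("ยา", N, "medicine"), ("ฝาดสมาน", Aj, "astrictive")],
        [("ยา", N, "medicine"), ("สมาน", Vs, "heal up"), ("แผล", N, "wound")],
    )
    entries += _prop(
        "Carminative",
        [("ยา", N, "medicine"), ("ขับ", Vs, "expel"), ("ลม", N, "gas")],
        [("ผายลม", Vs, "pass gas")],
    )
    entries += _prop(
        "Diaphoretic",
        [("สาร", N, "substance"), ("ขับ", Vs, "expel"), ("เหงื่อ", N, "sweat")],
        [("ขับ", Vs, "expel"), ("เหงื่อ", N, "sweat")],
    )
    entries += _prop(
        "Hypoglycemant",
        [("ยา", N, "medicine"), ("ลด", Vs, "reduce"), ("น้ำตาล", N, "sugar"),
         ("ใน", "Prep", "in"), ("เลือด", N, "blood")],
    )
    entries += _prop(
        "Vermifuge",
        [("ขับ", Vs, "expel"), ("พยาธิ", N, "parasite")],
        [("ฆ่า", Vs, "kill"), ("พยาธิ", N, "parasite")],
        [("ถ่าย", Vs, "excrete"), ("พยาธิ", N, "parasite")],
    )
    entries += _prop(
        "Vulnerary",
        [("รักษา", Vs, "cure"), ("บาดแผล", N, "wound")],
        [("สิ่ง", N, "thing"), ("รักษา", Vs, "cure"), ("แผล", N, "wound")],
    )
    return entries


#: Word-co keys each property concept must yield, exactly.
EXPECTED_PROPERTY_KEYS = {
    "Antidiarrhetic": {"แก้+ท้องเสีย", "รักษา+ท้องเสีย"},
    "Antiemetic": {"แก้+อาเจียน"},
    "Antihemorrhagic": {"ห้าม+เลือด", "แก้+เลือดออก"},
    "Anti-inflammatory": {"แก้+อักเสบ"},
    "Antipruritic": {"ลด+คัน", "แก้+คัน"},
    "Antipyretic": {"ลด+ไข้"},
    "Antitussive": {"บรรเทา+ไอ", "แก้+ไอ"},
    "Antiviral": {"ต้าน+เชื้อไวรัส", "ต้าน+ไวรัส"},
    "Aperient_laxative": {"เป็น+ยา+ระบาย", "เป็น+ยา+ถ่าย", "แก้+ท้องผูก"},
    "Astringent": {"เป็น+ยา+ฝาดสมาน", "สมาน+แผล"},
    "Carminative": {"ขับ+ลม", "ผายลม"},
    "Diaphoretic": {"ขับ+เหงื่อ"},
    "Hypoglycemant": {"ลด+น้ำตาล+เลือด"},
    "Vermifuge": {"ขับ+พยาธิ", "ฆ่า+พยาธิ", "ถ่าย+พยาธิ"},
    "Vulnerary": {"รักษา+บาดแผล", "รักษา+แผล"},
}


# ---------------------------------------------------------------------------
# Symptom terms
# ---------------------------------------------------------------------------

def _symp(label: str, *exprs: list[tuple[str, str, str]]) -> list[LexiconEntry]:
    return [
        LexiconEntry(label, tuple(expr), "symptom_term", entry_id=f"{label}:{k}")
        for k, expr in enumerate(exprs)
    ]


def symptom_lexicon() -> list[LexiconEntry]:
    N, Vs, Aj = "Noun", "V_strong", "Adj"
    entries: list[LexiconEntry] = []
    entries += _symp("flatulence", [("อาการ", N, "symptom"), ("ท้องเฟ้อ", Aj, "flatulence")])
    entries += _symp(
        "faint",
        [("วิงเวียน", Vs, "faint")],
        [("เป็นลม", Vs, "faint")],
    )
    entries += _symp("nausea", [("คลื่นไส้", Vs, "nauseate")])
    entries += _symp("sore throat", [("เจ็บ", Vs, "be sore"), ("คอ", N, "throat")])
    entries += _symp("skin disease", [("โรคผิวหนัง", N, "skin disease")])
    return entries


#: For each symptom concept, the slot part of the expected keys; the full
#: key set is {f"{ss}+{slots}" for ss in svc_sub} per variant.
EXPECTED_SYMPTOM_KEY_TEMPLATES = {
    "flatulence": ["ท้องเฟ้อ"],
    "faint": ["วิงเวียน", "เป็นลม"],
    "nausea": ["คลื่นไส้"],
    "sore throat": ["เจ็บ+คอ"],
    "skin disease": ["โรคผิวหนัง"],
}


# ---------------------------------------------------------------------------
# Thai-basil document excerpt (corpus dialect)
# ---------------------------------------------------------------------------

BASIL_DOCUMENT_TEXT = """\
#doc กะเพรา
#sec ใบ|Noun
มี|V_weak รส|Noun เผ็ดร้อน|Adj
ต้ม|V_strong เอา|V_weak น้ำดื่ม|Noun
เป็น|V_weak ยา|Noun ขับ|V_strong ลม|Noun
แก้|V_strong ท้องอืด|Adv ท้องเฟ้อ|Adv
แก้|V_strong ปวด|V_strong ท้อง|Noun
แก้|V_strong จุกเสียด|V_strong
แก้|V_strong คลื่นไส้|V_strong
ขับ|V_strong เสมหะ|Noun
นำ|V_weak ใบ|Noun สด|Adj บีบคั้น|V_strong น้ำ|Noun
ทา|V_strong
แก้|V_strong โรคผิวหนัง|Noun
"""

#: A gastrointestinal-disorder EDU whose pattern the lexicon cannot cover.
GASTRO_EDU_TOKENS = [
    ("ใช้", "V_weak"), ("รักษา", "V_strong"), ("โรค", "Noun"), ("มี", "V_weak"),
    ("อาการ", "Noun"), ("ผิดปกติ", "Adj"), ("ทางเดินอาหาร", "Noun"),
]


# ---------------------------------------------------------------------------
# Reference path-estimate table (27 part -> core-factor rows)
# ---------------------------------------------------------------------------

_PATH_ROWS = [
    ("pp_7", "FA", 0.163, 0.097, 1.682, 0.093),
    ("pp_7", "FB", 0.082, 0.046, 1.761, 0.078),
    ("pp_6", "FC", -0.157, 0.047, -3.342, 0.001),
    ("pp_6", "FA", 0.26, 0.085, 3.050, 0.002),
    ("pp_6", "FB", 0.063, 0.036, 1.748, 0.080),
    ("pp_5", "FA", 0.217, 0.085, 2.563, 0.010),
    ("pp_5", "FB", 0.078, 0.044, 1.773, 0.076),
    ("pp_5", "FC", -0.287, 0.066, -4.381, 0.001),
    ("pp_4", "FA", 0.219, 0.072, 3.040, 0.002),
    ("pp_4", "FB", 0.09, 0.050, 1.799, 0.072),
    ("pp_4", "FC", -0.278, 0.061, -4.566, 0.001),
    ("pp_3", "FA", 0.159, 0.133, 1.198, 0.231),
    ("pp_3", "FB", 0.113, 0.064, 1.761, 0.078),
    ("pp_3", "FC", -0.169, 0.068, -2.504, 0.012),
    ("pp_2", "FA", 0.819, 0.119, 6.908, 0.001),
    ("pp_2", "FB", 0.113, 0.063, 1.800, 0.072),
    ("pp_2", "FC", -0.360, 0.078, -4.611, 0.001),
    ("pp_1", "FA", 0.155, 0.082, 1.898, 0.058),
    ("pp_1", "FB", 0.099, 0.055, 1.796, 0.072),
    ("pp_1", "FC", -0.209, 0.053, -3.907, 0.001),
    ("pp_9", "FA", 0.864, 0.256, 3.372, 0.001),
    ("pp_9", "FB", 0.09, 0.059, 1.532, 0.126),
    ("pp_9", "FC", -0.497, 0.144, -3.460, 0.001),
    ("pp_8", "FA", 0.068, 0.076, 0.896, 0.370),
    ("pp_8", "FB", 0.109, 0.06, 1.805, 0.071),
    ("pp_8", "FC", -0.215, 0.053, -4.066, 0.001),
    ("pp_7", "FC", -0.267, 0.066, -4.029, 0.001),
]


def reference_path_estimates() -> list[PathEstimate]:
    """The 27 reference path rows as estimate objects."""
    return [
        PathEstimate(source=s, target=t, estimator=e, se=se, cr=cr, p=p)
        for s, t, e, se, cr, p in _PATH_ROWS
    ]


# ---------------------------------------------------------------------------
# Per-part SVM metric rows (Rhizome = pp_2, Leaf = pp_4)
# ---------------------------------------------------------------------------

SVM_PART_METRICS = {
    "Rhizome": {"accuracy": 0.79, "precision": 0.763, "recall": 0.728, "f1": 0.745},
    "Leaf": {"accuracy": 0.81, "precision": 0.770, "recall": 0.746, "f1": 0.758},
}


# ---------------------------------------------------------------------------
# Small plant table for graph lookups
# ---------------------------------------------------------------------------

FIG_PLANT_TABLE = [
    PlantRow("Basil", "Leaf", "Antiemetic"),
    PlantRow("Andrographis paniculata", "Leaf", "Antiemetic"),
    PlantRow("Cinnamon", "Leaf", "Antiemetic"),
    PlantRow("Basil", "Leaf", "relieveCold"),
    PlantRow("Andrographis paniculata", "Leaf", "relieveCold"),
    PlantRow("Fish mint", "Leaf", "relieveCold"),
    PlantRow("Lemonglass", "Leaf", "relieveCold"),
    PlantRow("Ginger", "Rhizome", "relieveCold"),
    PlantRow("Galangal", "Rhizome", "Carminative"),
]
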