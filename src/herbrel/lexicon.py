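"""Term lexicons, word sets and the medicinal-property-concept (MPC) table.

A medicinal property ("carminative", "antipyretic", ...) is expressed in the
source documents as a verb-anchored event: a solving verb (cure, reduce,
relieve, expel, ...) followed by up to three content words naming the problem
or symptom.  This module turns segmented lexicon entries into *word
co-occurrence expressions* of the form ``svc + w1 (+ w2 + w3)`` and collects
them into the MPC table, the lookup used later to recognise property mentions
in running text.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "POS_TAGS",
    "CONTENT_POS",
    "LexiconEntry",
    "WordSets",
    "WordCoExpression",
    "MPCFragment",
    "MPCTable",
    "SenseCandidate",
    "SenseChoice",
    "derive_word_co",
    "build_mpc_property",
    "build_mpc_symptom",
    "merge_dedupe",
    "select_sense",
    "read_lexicon",
    "write_lexicon",
]

#: Closed part-of-speech tag set used throughout the corpus dialect.
POS_TAGS = frozenset({"V_strong", "V_weak", "Noun", "Adj", "Adv", "Prep"})

#: Tags eligible to fill a w1/w2/w3 slot of the verb pattern.
CONTENT_POS = frozenset({"Noun", "Adj", "Adv", "V_strong"})


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon row: a concept label plus its segmented expression.

    ``segmented_expression`` is an ordered list of ``(token, pos, gloss)``
    triples; ``source_kind`` is ``"property_term"`` for entries drawn from a
    medicinal-property terminology and ``"symptom_term"`` for entries drawn
    from a medical-symptom list.
    """

    concept_label: str
    segmented_expression: tuple[tuple[str, str, str], ...]
    source_kind: str
    entry_id: str = ""

    def __post_init__(self) -> None:
        if not self.concept_label:
            raise ValueError("concept_label must be non-empty")
        if not self.segmented_expression:
            raise ValueError("segmented_expression must be non-empty")
        if self.source_kind not in ("property_term", "symptom_term"):
            raise ValueError(f"unknown source_kind: {self.source_kind!r}")
        for tok, pos, _ in self.segmented_expression:
            if pos not in POS_TAGS:
                raise ValueError(f"unknown POS tag {pos!r} on token {tok!r}")

    @property
    def tokens(self) -> list[tuple[str, str]]:
        """(token, pos) pairs, gloss dropped."""
        return [(t, p) for t, p, _ in self.segmented_expression]


@dataclass
class WordSets:
    """Configuration word sets driving pattern matching.

    svc
        Solving-verb expressions; each element is a tuple of one or two
        tokens (a strong verb, or a weak/strong verb plus a word, e.g.
        ``("เป็น", "ยา")`` "be medicine").
    svc_sub
        Subset of ``svc`` used to prefix symptom terms when building the
        MPC table.
    stop_words
        Tokens removed before pattern scanning.
    symptom_word
        The generic "symptom" noun, skipped during slot filling.
    wrd_set
        Gloss tokens used to disambiguate dictionary senses.
    pp_set
        Ordered plant-part inventory: list of ``{"label": ..., "tokens":
        [...]}`` records; position defines the part index pp_1..pp_n.
    """

    svc: list[tuple[str, ...]]
    svc_sub: list[tuple[str, ...]]
    stop_words: set[str]
    symptom_word: str
    wrd_set: set[str]
    pp_set: list[dict]

    def __post_init__(self) -> None:
        self.svc = [tuple(_nfc(t) for t in e) for e in self.svc]
        self.svc_sub = [tuple(_nfc(t) for t in e) for e in self.svc_sub]
        self.stop_words = {_nfc(t) for t in self.stop_words}
        self.symptom_word = _nfc(self.symptom_word)
        svc_set = set(self.svc)
        for e in self.svc_sub:
            if e not in svc_set:
                raise ValueError(f"svc_sub element {e!r} not in svc")
        if self.symptom_word in self.stop_words:
            raise ValueError("symptom_word must not be a stop word")
        labels = [p["label"] for p in self.pp_set]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate plant-part labels in pp_set")

    # -- lookup helpers -------------------------------------------------
    @property
    def part_labels(self) -> list[str]:
        return [p["label"] for p in self.pp_set]

    def part_of_token(self, token: str) -> Optional[str]:
        token = _nfc(token)
        for p in self.pp_set:
            if token in p["tokens"]:
                return p["label"]
        return None

    def svc_lead_is_strong(self, element: tuple[str, ...]) -> bool:
        """True when the element is a plain strong verb (not a weak-verb
        compound like "be + medicine")."""
        return len(element) == 1

    # -- serialization --------------------------------------------------
    def to_json(self) -> dict:
        return {
            "svc": [list(e) for e in self.svc],
            "svc_sub": [list(e) for e in self.svc_sub],
            "stop_words": sorted(self.stop_words),
            "symptom_word": self.symptom_word,
            "wrd_set": sorted(self.wrd_set),
            "pp_set": self.pp_set,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "WordSets":
        return cls(
            svc=[tuple(e) for e in obj["svc"]],
            svc_sub=[tuple(e) for e in obj["svc_sub"]],
            stop_words=set(obj["stop_words"]),
            symptom_word=obj["symptom_word"],
            wrd_set=set(obj["wrd_set"]),
            pp_set=list(obj["pp_set"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), ensure_ascii=False, indent=1),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordSets":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class WordCoExpression:
    """One verb-anchored co-occurrence expression: svc element + slot words."""

    svc_element: tuple[str, ...]
    slots: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.slots) > 4:
            raise ValueError("at most 4 content slots allowed")

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.svc_element) + tuple(self.slots)

    @property
    def key(self) -> str:
        return _nfc("+".join(self.components))


def derive_word_co(
    expr: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
    ws: WordSets,
) -> list[WordCoExpression]:
    """Scan a segmented expression for verb-anchored co-occurrence patterns.

    Stop words are removed first.  Solving-verb (svc) anchors are located by
    longest match, left to right; each anchor contributes one expression whose
    slots are the up-to-three content words (Noun/Adj/Adv/strong verb) that
    follow it.  The generic symptom word is never a slot.  A strong-verb
    anchor does not take a following svc strong verb as a slot (such verbs are
    coordinated alternatives and anchor their own expressions), whereas a
    weak-verb-led anchor does.  An anchor with no slots is emitted only when
    it spans the whole filtered expression (a standalone expression).
    """
    toks = [(_nfc(t[0]), t[1]) for t in expr if _nfc(t[0]) not in ws.stop_words]
    if not toks:
        return []

    # longest-match anchor scan
    by_len = sorted({len(e) for e in ws.svc}, reverse=True)
    svc_set = set(ws.svc)
    strong_singles = {e[0] for e in ws.svc if len(e) == 1}
    anchors: list[tuple[int, int]] = []  # (start, length)
    i = 0
    while i < len(toks):
        matched = 0
        for ln in by_len:
            cand = tuple(t for t, _ in toks[i : i + ln])
            if len(cand) == ln and cand in svc_set:
                matched = ln
                break
        if matched:
            anchors.append((i, matched))
            i += matched
        else:
            i += 1

    out: list[WordCoExpression] = []
    for start, ln in anchors:
        element = tuple(t for t, _ in toks[start : start + ln])
        lead_strong = ws.svc_lead_is_strong(element)
        slots: list[str] = []
        for tok, pos in toks[start + ln :]:
            if len(slots) == 3:
                break
            if tok == ws.symptom_word:
                continue
            if lead_strong and tok in strong_singles:
                continue
            if pos in CONTENT_POS and tok not in slots:
                slots.append(tok)
        if not slots and not (start == 0 and ln == len(toks)):
            continue
        out.append(WordCoExpression(element, tuple(slots)))
    return out


# ---------------------------------------------------------------------------
# MPC table construction
# ---------------------------------------------------------------------------

@dataclass
class MPCFragment:
    """Partial MPC table: key -> (concept label, provenance entry ids)."""

    entries: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    skip_report: list[dict] = field(default_factory=list)

    def add(self, key: str, concept: str, source: str) -> None:
        key = _nfc(key)
        self.entries.setdefault(key, concept)
        self.provenance.setdefault(key, [])
        if source not in self.provenance[key]:
            self.provenance[key].append(source)


@dataclass
class MPCTable:
    """The deduplicated lookup from word-co key to property concept."""

    entries: dict[str, str]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    conflicts: list[dict] = field(default_factory=list)
    skip_report: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def concepts(self) -> set[str]:
        return set(self.entries.values())

    def keys_for(self, concept: str) -> set[str]:
        return {k for k, c in self.entries.items() if c == concept}

    # -- CSV export (key, concept_label, provenance) --------------------
    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["key", "concept_label", "provenance"])
            for key in sorted(self.entries):
                w.writerow(
                    [key, self.entries[key], ";".join(self.provenance.get(key, []))]
                )

    @classmethod
    def load_csv(cls, path: str | Path) -> "MPCTable":
        entries: dict[str, str] = {}
        prov: dict[str, list[str]] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            r = csv.DictReader(fh)
            for row in r:
                key = _nfc(row["key"])
                entries[key] = row["concept_label"]
                prov[key] = [p for p in row.get("provenance", "").split(";") if p]
        return cls(entries=entries, provenance=prov)


def build_mpc_property(
    entries: Iterable[LexiconEntry], ws: WordSets
) -> MPCFragment:
    """Derive word-co keys from property-term entries.

    Each entry contributes the keys of :func:`derive_word_co` mapped to its
    concept label; entries yielding no key are recorded in the skip report.
    """
    frag = MPCFragment()
    for n, entry in enumerate(entries):
        if entry.source_kind != "property_term":
            raise ValueError(f"expected property_term entry, got {entry.source_kind}")
        eid = entry.entry_id or f"property:{n}:{entry.concept_label}"
        exprs = derive_word_co(entry.tokens, ws)
        if not exprs:
            frag.skip_report.append(
                {"entry": eid, "concept": entry.concept_label, "reason": "no word-co expression"}
            )
            continue
        for e in exprs:
            frag.add(e.key, entry.concept_label, eid)
    return frag


def build_mpc_symptom(
    entries: Iterable[LexiconEntry], ws: WordSets
) -> MPCFragment:
    """Prefix each symptom term with every solving verb of the svc subset.

    A symptom entry supplies the slot words (its content tokens after stop
    word and symptom-word removal); for every ``ss`` in ``svc_sub`` one key
    ``ss+w1(+w2+w3)`` is emitted, mapped to the concept ``ss+<label>``.
    """
    if not ws.svc_sub:
        raise ValueError("svc_sub is empty: configuration invalid")
    frag = MPCFragment()
    for n, entry in enumerate(entries):
        if entry.source_kind != "symptom_term":
            raise ValueError(f"expected symptom_term entry, got {entry.source_kind}")
        eid = entry.entry_id or f"symptom:{n}:{entry.concept_label}"
        slots: list[str] = []
        for tok, pos in entry.tokens:
            tok = _nfc(tok)
            if tok in ws.stop_words or tok == ws.symptom_word:
                continue
            if pos in CONTENT_POS and tok not in slots:
                slots.append(tok)
            if len(slots) == 3:
                break
        if not slots:
            frag.skip_report.append(
                {"entry": eid, "concept": entry.concept_label, "reason": "all tokens removed"}
            )
            continue
        for ss in ws.svc_sub:
            expr = WordCoExpression(ss, tuple(slots))
            concept = "+".join(ss) + "+" + entry.concept_label
            frag.add(expr.key, concept, eid)
    return frag


def merge_dedupe(*fragments: MPCFragment) -> MPCTable:
    """Merge fragments into one table, collapsing identical keys.

    When two fragments map one key to different concepts, the mapping coming
    from a property-term fragment wins (property terminology is the primary
    source) and the conflict is reported.  Property fragments must therefore
    be passed before symptom fragments; within equal precedence, first wins.
    """
    table = MPCTable(entries={}, provenance={})
    for frag in fragments:
        table.skip_report.extend(frag.skip_report)
        for key, concept in frag.entries.items():
            if key in table.entries and table.entries[key] != concept:
                table.conflicts.append(
                    {"key": key, "kept": table.entries[key], "dropped": concept}
                )
                continue
            table.entries[key] = concept
            for src in frag.provenance.get(key, []):
                table.provenance.setdefault(key, [])
                if src not in table.provenance[key]:
                    table.provenance[key].append(src)
    return table


# ---------------------------------------------------------------------------
# Sense selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SenseCandidate:
    """A dictionary sense: its gloss and the token set of its definition."""

    sense_gloss: str
    description_tokens: frozenset[str]

    def __post_init__(self) -> None:
        if not self.description_tokens:
            raise ValueError("description_tokens must be non-empty")


@dataclass(frozen=True)
class SenseChoice:
    sense: SenseCandidate
    confident: bool


def select_sense(candidates: Sequence[SenseCandidate], ws: WordSets) -> SenseChoice:
    """Pick the first sense whose definition mentions a health-domain word.

    Falls back to the first candidate, flagged low-confidence, when no
    definition intersects ``wrd_set``.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    for cand in candidates:
        if cand.description_tokens & ws.wrd_set:
            return SenseChoice(cand, confident=True)
    return SenseChoice(candidates[0], confident=False)


# ---------------------------------------------------------------------------
# Lexicon file I/O (UTF-8 TSV: concept_label, source_kind, tokens)
# ---------------------------------------------------------------------------

def read_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a TSV lexicon; tokens column holds ``token|POS|gloss`` triples
    separated by spaces (gloss may be empty)."""
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            label, kind, toks = parts
            seg = []
            for item in toks.split():
                bits = item.split("|")
                if len(bits) == 2:
                    bits.append("")
                if len(bits) != 3:
                    raise ValueError(f"{path}:{ln}: bad token {item!r}")
                seg.append((bits[0], bits[1], bits[2]))
            entries.append(
                LexiconEntry(label, tuple(seg), kind, entry_id=f"{Path(path).name}:{ln}")
            )
    return entries


def write_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            toks = " ".join(
                f"{t}|{p}|{g}" if g else f"{t}|{p}" for t, p, g in e.segmented_expression
            )
            fh.write(f"{e.concept_label}\t{e.source_kind}\t{toks}\n")
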