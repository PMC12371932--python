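"""Feature-vector extraction from a segmented herb corpus.

Streams each document while tracking the plant part named by the most recent
section header (or part mention), flags discourse units whose verb phrase
contains a solving verb, matches their word-co expressions against the MPC
table, and emits one symbolic / binary vector per (herb, plant part) group
plus the plant table of (herb, part, property) triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus_io import BinaryVector, Document, EDU, PlantRow, SymbolicVector
from .lexicon import MPCTable, WordSets, derive_word_co

__all__ = [
    "detect_plant_part",
    "is_medicinal_edu",
    "extract_medp",
    "run_extraction",
    "ExtractionResult",
]


def detect_plant_part(edu: EDU, ws: WordSets) -> Optional[str]:
    """Return the plant-part label named by the EDU's noun phrases.

    The first noun phrase is checked before the second; section-header EDUs
    (no verb phrase) are the primary carriers of part names.
    """
    for noun in (edu.np1_noun, edu.np2_noun):
        if noun is None:
            continue
        label = ws.part_of_token(noun)
        if label is not None:
            return label
    return None


def is_medicinal_edu(edu: EDU, ws: WordSets) -> bool:
    """True when the EDU's verb phrase contains a solving-verb element."""
    if not edu.has_vp:
        return False
    return bool(derive_word_co(edu.tokens, ws))


def extract_medp(edu: EDU, mpc: MPCTable, ws: WordSets) -> Optional[str]:
    """Match the EDU's word-co expressions against the MPC table.

    An MPC key matches when its component sequence occurs contiguously inside
    a derived expression's components; the longest matching key (component
    count, then text length) decides, so at most one property per EDU.
    """
    exprs = derive_word_co(edu.tokens, ws)
    if not exprs:
        return None
    best_key: Optional[str] = None
    best_rank = (-1, -1)
    for key in mpc.entries:
        comps = tuple(key.split("+"))
        rank = (len(comps), len(key))
        if rank <= best_rank:
            continue
        for e in exprs:
            ec = e.components
            n, m = len(ec), len(comps)
            if m > n:
                continue
            if any(ec[i : i + m] == comps for i in range(n - m + 1)):
                best_key, best_rank = key, rank
                break
    return mpc.entries[best_key] if best_key is not None else None


@dataclass
class ExtractionResult:
    symbolic: list[SymbolicVector]
    binary: list[BinaryVector]
    plant_rows: list[PlantRow]
    mp_index: list[str]
    skip_report: dict = field(default_factory=dict)


def run_extraction(
    corpus: Iterable[Document],
    mpc: MPCTable,
    ws: WordSets,
    mp_index: Optional[Sequence[str]] = None,
) -> ExtractionResult:
    """Run the full extraction over a corpus.

    For every matched (EDU, property) event under a current plant part, the
    property is appended to the open symbolic vector of that (herb, part)
    pair and a plant-table row is recorded.  EDUs before any part mention, or
    without a solving verb, are skipped.  Binarisation maps each (herb, part)
    group onto the global property index (first-appearance order unless
    ``mp_index`` is supplied).
    """
    if not mpc.entries:
        raise ValueError("MPC table is empty")

    symbolic: list[SymbolicVector] = []
    open_vectors: dict[tuple[str, str], SymbolicVector] = {}
    plant_rows: list[PlantRow] = []
    unmatched = 0
    skipped_no_part = 0
    medicinal = 0
    empty_docs = []

    for doc in corpus:
        current_ppart: Optional[str] = None
        doc_events = 0
        for edu in doc.edus:
            part = detect_plant_part(edu, ws)
            if part is not None:
                current_ppart = part
            if not edu.has_vp:
                continue
            if not is_medicinal_edu(edu, ws):
                continue
            medicinal += 1
            if current_ppart is None:
                skipped_no_part += 1
                continue
            medp = extract_medp(edu, mpc, ws)
            if medp is None:
                unmatched += 1
                continue
            key = (doc.herb_name, current_ppart)
            if key not in open_vectors:
                open_vectors[key] = SymbolicVector(doc.herb_name, current_ppart, [])
                symbolic.append(open_vectors[key])
            open_vectors[key].medp_list.append(medp)
            plant_rows.append(PlantRow(doc.herb_name, current_ppart, medp))
            doc_events += 1
        if doc_events == 0:
            empty_docs.append(doc.herb_name)

    # global property index: frozen first-appearance order, or supplied
    if mp_index is None:
        index: list[str] = []
        seen = set()
        for sv in symbolic:
            for medp in sv.medp_list:
                if medp not in seen:
                    seen.add(medp)
                    index.append(medp)
    else:
        index = list(mp_index)
        missing = {m for sv in symbolic for m in sv.medp_list} - set(index)
        if missing:
            raise ValueError(f"mp_index lacks extracted concepts: {sorted(missing)}")

    part_labels = ws.part_labels
    mp_pos = {m: j for j, m in enumerate(index)}
    binary: list[BinaryVector] = []
    for sv in symbolic:
        pp = np.zeros(len(part_labels), dtype=np.int8)
        pp[part_labels.index(sv.ppart)] = 1
        mp = np.zeros(len(index), dtype=np.int8)
        for medp in sv.medp_list:
            mp[mp_pos[medp]] = 1
        binary.append(BinaryVector(sv.hname, sv.ppart, pp, mp))

    return ExtractionResult(
        symbolic=symbolic,
        binary=binary,
        plant_rows=plant_rows,
        mp_index=index,
        skip_report={
            "medicinal_edus": medicinal,
            "unmatched_medicinal_edus": unmatched,
            "medicinal_edus_before_any_part": skipped_no_part,
            "documents_without_events": empty_docs,
        },
    )
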