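# herbrel

Mining **plant-part → medicinal-property-group** relations from segmented
herb documents.

Ethnopharmacology texts describe what each part of a medicinal plant does —
"leaves: carminative, relieves nausea, treats skin disease" — as event
sentences built around *solving verbs* (cure, reduce, relieve, expel, …).
`herbrel` turns such pre-segmented documents into structured knowledge for
researchers who want to ask: *which plant parts drive which groups of
medicinal properties, across many herbs at once?*

The pipeline:

1. **Lexicon → MPC table.** Each property/symptom term's segmented
   expression is scanned with a verb-anchored word co-occurrence pattern,
   `SVC + w1 (+ w2 + w3)` (≤ 5 words, stop words removed, the generic
   "symptom" noun skipped), producing lookup keys such as `ขับ+ลม` →
   *Carminative*. Symptom terms are additionally prefixed with every verb of
   a solving-verb subset.
2. **Extraction.** Documents are streamed EDU by EDU. Section headers set
   the current plant part `pp_i`; EDUs whose verb phrase contains a solving
   verb are matched against the MPC table (longest key wins, one property
   per EDU). Each (herb, part) group becomes a binary vector
   `⟨pp_1..pp_9, mp_1..mp_m⟩` and feeds a (herb, part, property) plant table.
3. **Hierarchical factor reduction.** The m correlated property indicators
   are reduced by principal-component extraction from the phi correlation
   matrix + varimax rotation; variables join the factor where their
   |loading| ≥ 0.4. Factor scores
   `FactorScore_z = Σ_j w_j (x_j − x̄_j)/SD_j`
   are reduced again to **core factors** (FA, FB, FC), named by properties
   with composite loading ≥ 0.5. Collapsing 88 properties to 3 groups cuts
   the 9×88 = 792 pair-testing space 29-fold.
4. **Path regression.** Each core-factor score is regressed on the part
   dummies, `F_l = β_0 + β_1 pp_1 + … + δ`; every path reports estimator,
   SE, critical ratio (t) and p. Paths with p < 0.05 are the extracted
   grouped relations; the sign says whether using the part improves
   (+) or tracks fewer (−) of the grouped symptoms.
5. **SVM baseline.** A soft-margin linear classifier
   `f(x) = ⟨w,x⟩ + b` over two-hot (part ⊕ property) encodings classifies
   individual pairs (`f(x) ≥ 0` → related), grouped per part and scored
   with accuracy/precision/recall/F1 and macro averages.
6. **Knowledge graph.** Relations become signed edges part → group; groups
   reachable from several parts are flagged *synergistic*; the plant table
   answers "which herbs give me (Leaf, Antiemetic)?". Export: JSON,
   GraphML, DOT.

A fully seeded synthetic generator (`herbrel.synthetic`) emulates the
study conditions — 20–130 EDUs per document, 9 parts, up to 88 properties
with planted correlation blocks and planted part→block path coefficients —
so every stage is testable end to end without any external data.

## Worked example

```bash
python examples/02_extract_vectors.py
```

```
document: กะเพรา  part: Leaf
matched properties: ['Carminative', 'แก้+nausea', 'แก้+skin disease']
binary vector: pp bits [0, 0, 0, 1, 0, 0, 0, 0, 0] | mp bits [1, 1, 1]
plant rows: [('กะเพรา', 'Leaf', 'Carminative'), ('กะเพรา', 'Leaf', 'แก้+nausea'), ('กะเพรา', 'Leaf', 'แก้+skin disease')]
skip report: {'medicinal_edus': 7, 'unmatched_medicinal_edus': 4, ...}
```

The Thai-basil excerpt's header sets the part to *Leaf* (pp_4); the EDU
"เป็น ยา ขับ ลม" (*[drink] as a carminative*) matches the key `ขับ+ลม`;
seven EDUs carry solving verbs, four of which have no lexicon coverage and
are counted as recall misses. `examples/04_path_relations.py` filters the
bundled 27-row reference path table down to 14 significant relations —
exactly two of them leaving the Leaf part (to FA, positive, and FC,
negative) — and re-estimates planted paths from scratch on synthetic data.
The other examples cover MPC construction, factor reduction, the SVM
baseline and graph export; `herbrel --help` exposes the same stages as a
CLI with a run manifest (`herbrel run --config run.json`).

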