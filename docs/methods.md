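# Methods

## The extraction model

The unit of analysis is the elementary discourse unit (EDU): a simple
sentence or clause of space-free, pre-segmented text with part-of-speech
tags from the closed set {V_strong, V_weak, Noun, Adj, Adv, Prep}. A
medicinal property is assumed to be expressed as an *event*: a solving verb
(an element of the SVC set — a strong verb, or a weak/strong verb plus one
word, e.g. "เป็น+ยา" *be medicine*) followed by at most three content words
naming the problem. The word-co pattern formalises this as
`SVC + w1 + w2 + w3` with `w ∈ Noun ∪ Adj ∪ Adv ∪ V_strong`, applied after
stop-word removal, with the generic symptom noun ("อาการ") skipped during
slot filling. Two committed readings resolve ambiguities in the pattern:

- A **strong-verb anchor does not take a following SVC strong verb as a
  slot word**: in "แก้ รักษา อาการ ท้องเสีย" the verbs แก้ and รักษา are
  coordinated alternatives, each anchoring its own expression
  (แก้+ท้องเสีย, รักษา+ท้องเสีย), never แก้+รักษา+ท้องเสีย. A
  **weak-verb-led anchor does** take a following strong verb as a slot
  (เป็น+ยา+ระบาย), because there the strong verb carries the property.
- An anchor with no slot words emits an expression only when it spans the
  entire filtered token sequence (standalone expressions such as ผายลม);
  otherwise one-verb fragments would flood the lookup table with
  over-general keys.

Matching at extraction time is component-substring matching: an MPC key
matches an EDU when its component sequence occurs *contiguously* inside one
of the EDU's derived expressions, and the longest matching key (component
count, then string length) wins, so each EDU contributes at most one
property. This is what lets the 2-component key ขับ+ลม fire inside the
4-component expression เป็น+ยา+ขับ+ลม. Multi-EDU property expressions
(anaphora across clauses) are deliberately not detected — a known recall
limitation of the single-EDU event model.

Plant-part state is a simple latch: the most recent part mention (usually a
section-header EDU carrying only a noun phrase) scopes all following
medicinal EDUs until the next mention. Documents may re-open a part; the
two sections accumulate into the same (herb, part) vector. EDUs before any
part mention are counted and skipped.

## Factor reduction

Binary property indicators are correlated by construction (herbs treat
families of related complaints), so the m-dimensional indicator space is
reduced in two stages, each using the same algorithm: Pearson (phi)
correlation matrix → eigendecomposition → top-k components scaled to
loadings → varimax rotation → hard assignment of each variable to its
max-|loading| factor provided |loading| ≥ 0.4 (ties to the lower factor
index; zero-variance columns dropped and reported). Principal-component
extraction was chosen over maximum-likelihood factor estimation for
determinism and because only the loading pattern (not SEs or fit indices)
is consumed downstream; phi over tetrachoric correlation for the same
reason. Factor signs are rotation-arbitrary, so each column is flipped to
make its largest-|loading| entry positive, and columns are ordered by
explained variance.

Varimax is run from the identity and from one fixed orthogonal starting
rotation, keeping the rotation with the larger criterion value: perfectly
symmetric loading patterns (two equal blocks at 45°) make the identity
start a saddle point at which the iteration stalls. Rotation preserves
communalities to 1e-8, which the tests assert.

Factor scores are the weighted standardized sums
`Σ_j w_j (x_j − x̄_j)/SD_j` over a factor's member variables, with w the
member's loading. A zero-SD member is an error naming the variable. The
second stage reduces the first-stage score matrix to core factors
(default 3, labelled FA, FB, FC); the default first-stage width is 15,
documenting the original 88 → 15 → 3 operating point. Core factors are
named by the properties whose *composite* loading — first-order loading ×
second-order loading of the property's factor — clears 0.5, joined in
descending order. The naming cut is applied to composite loadings, not
per-observation scores, since only loadings are observation-independent.

## Path model

The structural stage regresses each core-factor score on the plant-part
indicators by OLS with dummy coding: one reference part (default the last,
"Shoot") is dropped, plus an intercept, giving residual df = n − 9 for nine
parts. Estimator, classical SE, critical ratio (estimator/SE) and two-sided
Student-t p-value are reported per path; the reference part's own path
comes from a single releveled refit, so all nine parts receive estimates —
these are contrasts against the (releveled) reference, the standard
reading of dummy-coded paths. This two-stage procedure (factor scores,
then per-factor regressions) replaces a full covariance-based latent-
variable fit: it is deterministic, and the reported quantities are exactly
the regression outputs. The per-indicator disturbance terms of the
structural notation are absorbed into the single equation residual. Exact
fits (zero residual variance) flag the ratio as degenerate rather than
reporting an infinite t; parts with zero observations are flagged not
estimable. Relations are the paths with p < α (default 0.05), signed by
the estimator.

## SVM baseline

The comparison method learns individual (part, property) pairs. The input
encoding — one-hot part concatenated with one-hot property, exactly two
bits set — is the minimal encoding consistent with treating both features
as the classifier's inputs; one instance is emitted per (vector, set bit)
event so a pair can carry both labels across a corpus. Training uses a
soft-margin linear SVM (scikit-learn SVC, linear kernel); the decision
rule is `f(x) ≥ 0 → related`, inclusive at the boundary. A seeded
stratified 10-fold harness pools out-of-fold predictions, computes per-part
accuracy/precision/recall/F1 and unweighted macro averages (3-decimal
rounding by default).

## Synthetic generator

The generator defines the study conditions for all statistical tests:
259 documents of 20–130 EDUs, 9 plant parts, 88 property concepts, 600
direct binary observations, three planted correlation blocks of 8
properties each. Pseudo-tokens ("v03", "n217") replace natural-language
text so unicode handling is tested separately on the hand-transcribed Thai
examples. Two generation routes:

- **Corpus route** (`gen_corpus`): documents with part headers, medicinal
  EDUs realising sampled (part, property) events through lexicon surface
  forms (each block member included with probability 0.7 once a block is
  chosen), and distractor EDUs without solving verbs. Surface realisation
  is noise-free, so extraction against the generated lexicon must achieve
  precision = recall = 1.0 — this validates the extractor, not robustness
  to noisy text.
- **Vector route** (`gen_vectors`): per observation a part is drawn
  uniformly; each block latent is the planted path coefficient of that part
  plus N(0,1); block members threshold
  `0.9·latent + √(1−0.9²)·N(0,1) > 0` to binary (within-block phi ≈ 0.6);
  non-block properties are Bernoulli(0.15) background. Planted path
  coefficients default to +0.8 on two parts and −0.4 on one. At n = 600
  with ~67 observations per part the +0.8 paths are detected essentially
  always and the −0.4 path with ≈ 0.6 power, so pooled sign-recovery power
  sits near 0.88 against the ≥ 0.8 acceptance bar.

What passing these tests does *not* show: robustness to segmentation
errors, unseen surface variants, translation noise, or multi-EDU
expressions — the generator realises every event through a known lexicon
entry, whereas real corpora do not.

## Numerical choices and degenerate inputs

- Keys are NFC-normalized exact token joins with "+", for bit-stable
  lookup across platforms.
- Key conflicts during table merging keep the first (property-term)
  mapping and log the conflict; merging is idempotent.
- Sense selection returns the first candidate whose dictionary definition
  intersects the health-domain word set; no intersection → first candidate,
  flagged low-confidence.
- The property index used for binarization is frozen in first-appearance
  order (or loaded from file), making extraction byte-deterministic.
- Stemming is a pluggable no-op: corpora are assumed lemmatized upstream.
- Recovery studies use problem sizes of 20 seeds (purity), 50 seeds
  (power) and 1000 replicates (type-I calibration, one latent target per
  replicate) at n = 600 — large enough for stable rates, small enough that
  the full suite runs in seconds.

## Known limitations

Single-EDU, verb-anchored events only; hard factor assignment (a property
belongs to at most one factor); dummy-coded contrasts rather than a latent
covariance model, so coefficient magnitudes are relative to the reference
part; the SVM baseline assumes pair labels are available (from supervision
or generator ground truth); graphs render edge sign as an attribute, not
direction.
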